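"""End-to-end orchestration: soil -> rhizosphere -> root analysis.

``run_all`` executes the stages in study order — diversity, ordination +
group tests, biomarkers, assembly null models, networks, functions — over
either a synthetic fixture (generated in place) or user-supplied inputs,
writing per-stage TSVs and a JSON manifest (config snapshot, input/output
SHA-256 digests, stage statuses, master seed, version). Re-running with the
same inputs and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from ._rng import substream
from .assembly import assembly_analysis, process_fractions
from .biomarkers import lefse_from_otus
from .diversity import (alpha_diversity, alpha_group_tests, anosim,
                        bray_curtis, nmds, permanova_two_way)
from .functions import compare_functions, map_functions, read_function_map
from .io import (AnalysisConfig, OtuTable, SampleMetadata, ValidationError,
                 read_metadata, read_otu_table, read_tree, write_table)
from .networks import build_network, keystone_taxa, network_topology, \
    write_network
from .simulate import SimulationParams, generate_fixture_set

log = logging.getLogger("rootniche")

STAGES = ("diversity", "ordination", "permanova", "biomarkers", "assembly",
          "network", "functions")
KINGDOMS = ("bacteria", "fungi")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(indir: Path) -> dict:
    inputs = {"metadata": read_metadata(indir / "metadata.tsv")}
    for kingdom in KINGDOMS:
        otu = indir / f"otu_{kingdom}.tsv"
        if not otu.exists():
            raise ValidationError(f"missing OTU table: {otu}")
        inputs[f"table_{kingdom}"] = read_otu_table(otu, kingdom=kingdom)
        tree = indir / f"tree_{kingdom}.nwk"
        inputs[f"tree_{kingdom}"] = read_tree(tree) if tree.exists() else None
        fmap = indir / f"function_map_{kingdom}.tsv"
        inputs[f"fmap_{kingdom}"] = (read_function_map(fmap)
                                     if fmap.exists() else None)
    return inputs


def run_all(outdir, seed: int = 0, config: AnalysisConfig | None = None,
            stages=None, input_dir=None,
            sim_params: SimulationParams | None = None) -> Path:
    """Run the pipeline; returns the output directory.

    Without ``input_dir`` a synthetic fixture is generated under
    ``outdir/fixture`` first. ``stages`` selects a subset of :data:`STAGES`;
    skipped stages are recorded in the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or AnalysisConfig(rng_seed=seed)
    selected = list(stages) if stages else list(STAGES)
    unknown = set(selected) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": dataclasses.asdict(config),
        "stages": {},
        "inputs": {},
        "outputs": {},
    }

    if input_dir is None:
        fixdir = outdir / "fixture"
        log.info("simulating fixture set in %s", fixdir)
        objects = generate_fixture_set(fixdir, seed=seed, params=sim_params)
        manifest["stages"]["simulate"] = "ok"
        input_dir = fixdir
    else:
        objects = None
        manifest["stages"]["simulate"] = "skipped (inputs supplied)"
    input_dir = Path(input_dir)
    inputs = _load_inputs(input_dir) if objects is None else objects
    for f in sorted(input_dir.iterdir()):
        if f.is_file():
            manifest["inputs"][f.name] = _sha256(f)

    meta: SampleMetadata = inputs["metadata"]
    written: list[Path] = []

    def emit(df, name, index=True):
        path = outdir / name
        write_table(df, path, index=index)
        written.append(path)

    def stage(name):
        return name in selected

    try:
        current = None
        for kingdom in KINGDOMS:
            table: OtuTable = inputs[f"table_{kingdom}"]
            tree = inputs.get(f"tree_{kingdom}")
            sseed = int(substream(seed, "stage", kingdom).integers(2 ** 31))

            if stage("diversity"):
                current = "diversity"
                alpha = alpha_diversity(table)
                emit(alpha, f"alpha_{kingdom}.tsv")
                tests = alpha_group_tests(alpha, meta)
                emit(tests["pairwise"], f"alpha_tests_{kingdom}.tsv",
                     index=False)

            dist = None
            if stage("ordination") or stage("permanova"):
                dist = bray_curtis(table)
            if stage("ordination"):
                current = "ordination"
                ord_res = nmds(dist, k=2, seed=sseed)
                coords = ord_res.coordinates.copy()
                coords["stress"] = ord_res.stress
                emit(coords, f"nmds_{kingdom}.tsv")
                an = anosim(dist, meta.niche(), n_perm=config.n_permutations,
                            seed=sseed)
                emit(pd.DataFrame([{"R": an.statistic, "p": an.p_value,
                                    "n_permutations": an.n_permutations}]),
                     f"anosim_{kingdom}.tsv", index=False)
            if stage("permanova"):
                current = "permanova"
                pr = permanova_two_way(dist, meta.niche(), meta.cultivar(),
                                       n_perm=config.n_permutations,
                                       seed=sseed,
                                       names=("niche", "cultivar"))
                emit(pr.table, f"permanova_{kingdom}.tsv")

            if stage("biomarkers"):
                current = "biomarkers"
                bio = lefse_from_otus(table, meta, config)
                emit(bio, f"biomarkers_{kingdom}.tsv", index=False)

            if stage("assembly"):
                current = "assembly"
                if tree is None:
                    raise ValidationError(
                        f"assembly stage requires tree_{kingdom}.nwk")
                pairs = assembly_analysis(table, tree, meta,
                                          n_null=config.n_null, seed=sseed)
                emit(pairs, f"assembly_pairs_{kingdom}.tsv", index=False)
                emit(process_fractions(pairs),
                     f"process_fractions_{kingdom}.tsv")

            if stage("network"):
                current = "network"
                net = build_network(table, config)
                write_network(net, outdir / f"network_{kingdom}.graphml",
                              outdir / f"network_{kingdom}_edges.tsv")
                written += [outdir / f"network_{kingdom}.graphml",
                            outdir / f"network_{kingdom}_edges.tsv"]
                topo = network_topology(net)
                emit(pd.json_normalize(topo), f"topology_{kingdom}.tsv",
                     index=False)
                if net.n_nodes:
                    emit(keystone_taxa(net), f"keystones_{kingdom}.tsv",
                         index=False)

            if stage("functions"):
                current = "functions"
                fmap = inputs.get(f"fmap_{kingdom}")
                if fmap is None:
                    raise ValidationError(
                        f"functions stage requires function_map_{kingdom}.tsv")
                ftab = map_functions(table, fmap)
                emit(ftab, f"functions_{kingdom}.tsv")
                emit(compare_functions(ftab, meta),
                     f"function_tests_{kingdom}.tsv")

        if stage("network"):
            current = "network"
            inter = build_network([inputs["table_bacteria"],
                                   inputs["table_fungi"]], config)
            write_network(inter, outdir / "network_interkingdom.graphml",
                          outdir / "network_interkingdom_edges.tsv")
            written += [outdir / "network_interkingdom.graphml",
                        outdir / "network_interkingdom_edges.tsv"]
            emit(pd.json_normalize(network_topology(inter)),
                 "topology_interkingdom.tsv", index=False)
    except Exception as exc:
        for s in STAGES:
            if s not in manifest["stages"]:
                manifest["stages"][s] = (
                    f"failed: {exc}" if s == current
                    else ("not run" if s in selected else "skipped"))
        _write_manifest(manifest, written, outdir)
        raise StageError(f"stage {current!r} failed: {exc}") from exc

    for s in STAGES:
        manifest["stages"][s] = "ok" if s in selected else "skipped"
    _write_manifest(manifest, written, outdir)
    return outdir


def _write_manifest(manifest, written, outdir: Path) -> None:
    for path in written:
        if path.exists():
            manifest["outputs"][path.name] = _sha256(path)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
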