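"""Pipeline orchestration: simulate -> assemble -> qc -> quant [-> snv -> fusion].

A single YAML/dict config with one block per stage drives the run; the
global seed propagates into the simulator block.  Every output file is
checksummed into a manifest, so identical config + seed gives identical
manifests.  A failing stage stops the run with a non-zero status and leaves
upstream outputs in place.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time

import pandas as pd

from . import io as sio
from .annotation import ToyAnnotation
from .assembly import AssemblyParams, assemble_all, bin_reads, write_slr_fastq
from .sim import SimConfig, simulate_dataset

log = logging.getLogger("slrtx")

STAGES = ("simulate", "assemble", "qc", "quant", "snv", "fusion")


class ConfigError(ValueError):
    pass


def default_config() -> dict:
    return {
        "seed": 0,
        "stages": {s: s in ("simulate", "assemble", "qc", "quant") for s in STAGES},
        "simulate": dataclasses.asdict(SimConfig()),
        "assembly": dataclasses.asdict(AssemblyParams()),
        "qc": {"end_window": 100, "min_length": 700, "max_divergence": 0.3},
        "quant": {"junction_tolerance": 5},
        "snv": {"variants": None, "groups": None},
        "fusion": {"table": None},
        "inputs": {"reads": None},
    }


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for k, v in override.items():
        if k not in base:
            raise ConfigError(f"unknown config field {path + k}")
        if isinstance(base[k], dict) and isinstance(v, dict):
            out[k] = _merge(base[k], v, path + k + ".")
        else:
            out[k] = v
    return out


def load_config(config: dict | None) -> dict:
    cfg = _merge(default_config(), config or {})
    sim = dict(cfg["simulate"])
    sim["seed"] = cfg["seed"]
    for key in ("exon_length", "intron_length"):
        if isinstance(sim.get(key), list):
            sim[key] = tuple(sim[key])
    if isinstance(sim.get("abundance"), list):
        sim["abundance"] = tuple(sim["abundance"])
    try:
        cfg["simulate"] = SimConfig(**sim)
        cfg["simulate"].validate()
        cfg["assembly"] = AssemblyParams(**cfg["assembly"])
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict | None, out_dir: str) -> tuple[int, dict]:
    """Run the configured stages; returns (exit status, manifest).

    Status 0 = success, 1 = invalid configuration, 2 = missing input file.
    """
    try:
        cfg = load_config(config)
    except ConfigError as exc:
        log.error("invalid config: %s", exc)
        return 1, {"error": str(exc)}

    for name, path in (cfg.get("inputs") or {}).items():
        if path is not None and not os.path.exists(path):
            log.error("missing input file for %s: %s", name, path)
            return 2, {"error": f"missing input: {path}"}
    for name, key in (("snv", "variants"), ("fusion", "table")):
        path = cfg[name].get(key)
        if cfg["stages"].get(name) and path is not None and not os.path.exists(path):
            log.error("missing input file for %s: %s", name, path)
            return 2, {"error": f"missing input: {path}"}

    os.makedirs(out_dir, exist_ok=True)
    fh = logging.FileHandler(os.path.join(out_dir, "run.log"))
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    outputs: dict[str, str] = {}
    state: dict = {}
    try:
        for stage in STAGES:
            if not cfg["stages"].get(stage):
                continue
            t0 = time.time()
            log.info("stage %s started", stage)
            _RUNNERS[stage](cfg, out_dir, outputs, state)
            log.info("stage %s done in %.1fs", stage, time.time() - t0)
    except FileNotFoundError as exc:
        log.error("stage failed, missing file: %s", exc)
        return 2, _manifest(cfg, outputs, out_dir)
    except Exception as exc:  # preserve upstream outputs on partial failure
        log.exception("stage failed: %s", exc)
        return 3, _manifest(cfg, outputs, out_dir)
    finally:
        log.removeHandler(fh)
        fh.close()
    manifest = _manifest(cfg, outputs, out_dir)
    with open(os.path.join(out_dir, "manifest.json"), "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return 0, manifest


def _manifest(cfg: dict, outputs: dict[str, str], out_dir: str) -> dict:
    return {
        "seed": cfg["seed"] if isinstance(cfg, dict) and "seed" in cfg else None,
        "files": {
            name: {"path": os.path.relpath(p, out_dir), "sha256": _sha256(p)}
            for name, p in sorted(outputs.items())
            if os.path.exists(p)
        },
    }


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------


def _run_simulate(cfg, out_dir, outputs, state):
    from .sim import write_dataset

    res = simulate_dataset(cfg["simulate"])
    paths = write_dataset(res, out_dir)
    outputs.update({f"sim/{k}": v for k, v in paths.items()})
    state["sim"] = res
    state["annotation"] = res.annotation
    state["references"] = {
        i: res.annotation.spliced_sequence(i) for i in res.annotation.isoforms
    }


def _run_assemble(cfg, out_dir, outputs, state):
    if "sim" in state:
        reads = state["sim"].reads
    else:
        path = (cfg.get("inputs") or {}).get("reads")
        if path is None:
            raise ConfigError("assemble stage needs simulated reads or inputs.reads")
        reads = list(sio.read_fastq(path))
    bins = bin_reads(reads)
    contigs, rejected = assemble_all(bins, cfg["assembly"])
    slr_path = os.path.join(out_dir, "slr.fastq")
    write_slr_fastq(slr_path, contigs)
    rej_path = os.path.join(out_dir, "rejected_bins.tsv")
    pd.DataFrame(
        [(r.sample_index, r.umi, r.n_reads, r.reason) for r in rejected],
        columns=["sample_index", "umi", "n_reads", "reason"],
    ).to_csv(rej_path, sep="\t", index=False)
    outputs["assemble/slr"] = slr_path
    outputs["assemble/rejected"] = rej_path
    state["contigs"] = contigs


def _require_contigs(state):
    if "contigs" not in state:
        raise ConfigError("stage needs assembled contigs (enable the assemble stage)")
    return [c for c in state["contigs"] if c.completeness == "full_length"]


def _run_qc(cfg, out_dir, outputs, state):
    from .align import align_to_reference
    from .qc import (
        compare_abundance,
        compute_on_target,
        detect_chimeras,
        profile_errors,
        terminus_offsets,
    )

    full = _require_contigs(state)
    refs = state["references"]
    ref_len = {k: len(v) for k, v in refs.items()}
    inserts = {c.contig_id: c.insert for c in full if c.insert}
    qc_cfg = cfg["qc"]

    chim = detect_chimeras(inserts, refs, end_window=qc_cfg["end_window"])
    chim_path = os.path.join(out_dir, "chimera_report.tsv")
    chim.verdicts.to_csv(chim_path, sep="\t", index=False)

    clean_ids = set(chim.verdicts.loc[chim.verdicts.verdict == "clean", "contig_id"])
    records, unaligned = align_to_reference(
        {k: v for k, v in inserts.items() if k in clean_ids},
        refs,
        max_divergence=qc_cfg["max_divergence"],
    )
    prof = profile_errors(records, ref_len)
    sum_path = os.path.join(out_dir, "error_summary.tsv")
    pd.DataFrame([prof.summary()]).to_csv(sum_path, sep="\t", index=False)

    term = terminus_offsets(records, ref_len)
    term_path = os.path.join(out_dir, "terminus_offsets.tsv")
    term.per_contig.to_csv(term_path, sep="\t", index=False)

    obs: dict[str, int] = {}
    for rec in records:
        obs[rec.ref_id] = obs.get(rec.ref_id, 0) + 1
    expected = pd.DataFrame(
        {
            "id": sorted(refs),
            "expected": [
                max(1e-9, 1.0 / len(refs)) for _ in refs
            ],
            "length": [len(refs[i]) for i in sorted(refs)],
        }
    )
    ab = compare_abundance(obs, expected, min_length=qc_cfg["min_length"])
    ab_path = os.path.join(out_dir, "abundance.tsv")
    ab.table.to_csv(ab_path, sep="\t", index=False)

    # on-target against the target BED: genome intervals are projected to
    # transcript space as whole-transcript targets of the genes they name
    bed = os.path.join(out_dir, "targets.bed")
    ot = {"read_level": 0.0, "base_level": 0.0}
    if os.path.exists(bed):
        ann: ToyAnnotation = state["annotation"]
        named: set[str] = set()
        with open(bed) as f:
            for line in f:
                parts = line.split("\t")
                if len(parts) >= 4:
                    named.add(parts[3].strip())
        i2g = ann.iso_to_gene()
        targets = [
            (iso, 0, ref_len[iso])
            for iso in sorted(refs)
            if i2g.get(iso) in named
        ]
        ot = compute_on_target(records, targets)
    ot_path = os.path.join(out_dir, "on_target.tsv")
    pd.DataFrame([ot]).to_csv(ot_path, sep="\t", index=False)

    outputs.update(
        {
            "qc/chimera": chim_path,
            "qc/error_summary": sum_path,
            "qc/terminus": term_path,
            "qc/abundance": ab_path,
            "qc/on_target": ot_path,
        }
    )
    state["qc_records"] = records
    state["clean_ids"] = clean_ids


def _run_quant(cfg, out_dir, outputs, state):
    from .isoform import assign_contigs, build_count_matrices

    full = _require_contigs(state)
    ann: ToyAnnotation = state["annotation"]
    by_sample: dict[str, dict[str, str]] = {}
    for c in full:
        if c.insert:
            by_sample.setdefault(c.sample_index, {})[c.contig_id] = c.insert
    assignments = {
        s: assign_contigs(cs, ann, cfg["quant"]["junction_tolerance"])
        for s, cs in sorted(by_sample.items())
    }
    iso, gene = build_count_matrices(assignments, ann)
    iso_path = os.path.join(out_dir, "counts_isoform.tsv")
    gene_path = os.path.join(out_dir, "counts_gene.tsv")
    iso.to_csv(iso_path, sep="\t")
    gene.to_csv(gene_path, sep="\t")
    outputs["quant/isoform"] = iso_path
    outputs["quant/gene"] = gene_path
    state["assignments"] = assignments


def _run_snv(cfg, out_dir, outputs, state):
    from .snv import pileup_by_isoform, read_variants, test_distribution_shift, test_uneven_distribution

    variants_path = cfg["snv"].get("variants")
    if variants_path is None:
        log.info("snv stage skipped: no variants table configured")
        return
    variants = read_variants(variants_path)
    ann = state["annotation"]
    full = {c.contig_id: c for c in _require_contigs(state)}
    contigs_by_sample: dict[str, list] = {}
    for sample, asns in state["assignments"].items():
        rows = [
            (a.contig_id, a.isoform_id, full[a.contig_id].insert)
            for a in asns
            if a.status == "assigned"
        ]
        contigs_by_sample[sample] = rows
    matrix = pileup_by_isoform(contigs_by_sample, variants, ann)
    mat_path = os.path.join(out_dir, "snv_isoform_matrix.tsv")
    matrix.to_csv(mat_path, sep="\t", index=False)
    screens = pd.concat(
        [test_uneven_distribution(matrix), test_distribution_shift(matrix)],
        ignore_index=True,
    )
    scr_path = os.path.join(out_dir, "snv_screens.tsv")
    screens.to_csv(scr_path, sep="\t", index=False)
    outputs["snv/matrix"] = mat_path
    outputs["snv/screens"] = scr_path


def _run_fusion(cfg, out_dir, outputs, state):
    from .fusion import (
        build_junction_library,
        candidates_table,
        detect_novel_fusions,
        filter_novel_fusions,
        search_junctions,
    )

    full = _require_contigs(state)
    ann = state["annotation"]
    inserts = {c.contig_id: c.insert for c in full if c.insert}
    table_path = cfg["fusion"].get("table") or os.path.join(out_dir, "fusion_table.tsv")
    rows = []
    if os.path.exists(table_path):
        lib = build_junction_library(pd.read_csv(table_path, sep="\t"))
        if len(lib):
            hits = search_junctions(inserts, lib)
            rows = [
                {"contig_id": h.contig_id, "fusion_id": h.fusion_id, "offset": h.offset, "strand": h.strand}
                for h in hits
            ]
    hits_path = os.path.join(out_dir, "fusion_hits.tsv")
    pd.DataFrame(rows, columns=["contig_id", "fusion_id", "offset", "strand"]).to_csv(
        hits_path, sep="\t", index=False
    )
    cands = filter_novel_fusions(detect_novel_fusions(inserts, ann), ann)
    cand_path = os.path.join(out_dir, "fusion_candidates.tsv")
    candidates_table(cands).to_csv(cand_path, sep="\t", index=False)
    outputs["fusion/hits"] = hits_path
    outputs["fusion/candidates"] = cand_path


_RUNNERS = {
    "simulate": _run_simulate,
    "assemble": _run_assemble,
    "qc": _run_qc,
    "quant": _run_quant,
    "snv": _run_snv,
    "fusion": _run_fusion,
}
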