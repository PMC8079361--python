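"""Shared fixtures: simulated datasets at the scales the checks need.

The expensive ERCC-style run (single-isoform genes with distinct sequences,
realistic error/artefact rates) is session-scoped and shared by the
consensus-accuracy, chimera and terminus checks.
"""
from __future__ import annotations

import numpy as np
import pytest

from slrtx.assembly import AssemblyParams, assemble_all, bin_reads
from slrtx.sim import SimConfig, build_toy_annotation, sample_molecules, simulate_dataset


@pytest.fixture(scope="session")
def ercc_run():
    """ERCC-like library: 20 distinct mono-exon references, 500 molecules,
    depth 25, short-read substitution rate 4e-3, 2% chimeras, 13% premature
    termination, 15.6% TTS mis-priming."""
    cfg = SimConfig(
        n_genes=20,
        isoforms_per_gene=1,
        exons_per_gene=1,
        exon_length=(500, 1500),
        n_molecules=500,
        coverage_depth=25,
        sub_rate=4e-3,
        ins_rate=4e-4,
        del_rate=4.8e-4,
        chimera_rate=0.02,
        premature_termination_prob=0.13,
        tts_mispriming_prob=0.156,
        seed=101,
    )
    res = simulate_dataset(cfg)
    contigs, rejected = assemble_all(bin_reads(res.reads), AssemblyParams())
    return res, contigs, rejected


@pytest.fixture(scope="session")
def ercc_full_length(ercc_run):
    res, contigs, _ = ercc_run
    truth = {f"{m.sample_index}:{m.umi}": m for m in res.molecules}
    full = [c for c in contigs if c.completeness == "full_length" and c.umi in
            {m.umi for m in res.molecules}]
    return res, [c for c in full if c.contig_id in truth], truth


@pytest.fixture(scope="session")
def multi_isoform_annotation():
    cfg = SimConfig(
        n_genes=4,
        isoforms_per_gene=3,
        exons_per_gene=5,
        seed=3,
        premature_termination_prob=0.0,
        tts_mispriming_prob=0.0,
        chimera_rate=0.0,
    )
    return cfg, build_toy_annotation(cfg)


@pytest.fixture(scope="session")
def multi_isoform_molecules(multi_isoform_annotation):
    cfg, ann = multi_isoform_annotation
    return ann, sample_molecules(ann, cfg, rng=np.random.default_rng(12))


@pytest.fixture(scope="session")
def fusion_annotation():
    cfg = SimConfig(
        n_genes=6, isoforms_per_gene=1, exons_per_gene=4, fusions=True, seed=5
    )
    return cfg, build_toy_annotation(cfg)
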