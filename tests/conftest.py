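"""Shared fixtures: synthetic study runs at two scales.

``small_*`` fixtures use a reduced study (6 planted genes, 30k reads) for
fast unit/integration tests; ``default_run`` executes the full default
synthetic study (20 genes, 2x200k reads) once per session for the
recovery-oriented tests.
"""

from __future__ import annotations

import dataclasses

import pytest

from mirnaome.annotate import match_known_mirnas, match_ncrna, match_transcripts
from mirnaome.hairpin import discover_novel
from mirnaome.reads import process_libraries
from mirnaome.simulate import SimulationConfig, build_references, simulate_libraries

# Reduced study for fast tests: abundances scaled up so that miRNA* arms
# are still sequenced at >= min_count in 30k-read libraries.
SMALL_CONFIG = SimulationConfig(
    seed=7, n_mirnas=6, n_known=3, n_transcripts=60,
    transcript_len_range=(500, 1200), n_noncoding_refs=8,
    library_sizes=(30_000, 30_000),
    abundance_range=(1000.0, 3000.0), star_fraction=0.25,
)

DEFAULT_SEED = 11


@pytest.fixture(scope="session")
def small_config():
    return dataclasses.replace(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_refs(small_config):
    return build_references(small_config)


@pytest.fixture(scope="session")
def small_sim(small_refs, small_config, tmp_path_factory):
    """References on disk plus a simulated FASTQ pair (small scale)."""
    outdir = tmp_path_factory.mktemp("small_sim")
    paths = small_refs.write(outdir / "refs")
    fa, fb = simulate_libraries(small_refs, small_config, outdir)
    return {"refs": small_refs, "config": small_config, "paths": paths,
            "fastq_a": fa, "fastq_b": fb, "outdir": outdir}


@pytest.fixture(scope="session")
def small_table(small_sim):
    table, stats = process_libraries(
        small_sim["fastq_a"], small_sim["fastq_b"],
        small_sim["config"].adapter_5p, small_sim["config"].adapter_3p)
    return table


def _run_study(config, tmp_path):
    refs = build_references(config)
    fa, fb = simulate_libraries(refs, config, tmp_path)
    table, stats = process_libraries(fa, fb, config.adapter_5p, config.adapter_3p)
    ncrna_asg = match_ncrna(table, refs.ncrna)
    known_asg = match_known_mirnas(table, refs.mature_catalog)
    transcript_asg = match_transcripts(table, refs.transcripts)
    consumed = set(ncrna_asg) | set(known_asg)
    candidates = sorted(s for s in transcript_asg if s not in consumed)
    calls = discover_novel(table, candidates, refs.transcripts)
    return {"config": config, "refs": refs, "table": table, "stats": stats,
            "ncrna_asg": ncrna_asg, "known_asg": known_asg,
            "transcript_asg": transcript_asg, "calls": calls,
            "fastq_a": fa, "fastq_b": fb}


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full default synthetic study: 10 known + 10 novel genes, 2 x 200k reads."""
    outdir = tmp_path_factory.mktemp("default_run")
    return _run_study(SimulationConfig(seed=DEFAULT_SEED), outdir)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("small_run")
    return _run_study(dataclasses.replace(SMALL_CONFIG), outdir)
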