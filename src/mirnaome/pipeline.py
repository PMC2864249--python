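"""End-to-end orchestration: trim -> filter -> classify -> discover -> test -> targets.

`run_all` executes the full comparative-miRNAome workflow on a pair of
small-RNA libraries and three references (transcripts, ncRNA catalogue,
mature-miRNA catalogue), writing the classification summary, known- and
novel-miRNA tables, the differential profile, target predictions, hotspot
statistics, precursor structures and a machine-readable run manifest.  The
stage order is fixed because category precedence depends on it: ncRNA
classes are removed first, known miRNAs assigned next, novel candidates
(structure + miRNA* evidence) third, coding-gene orientation last.  All
outputs are deterministic functions of the config and inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from ._seq import to_dna
from .annotate import (categorize, category_summary, match_known_mirnas,
                       match_ncrna, match_transcripts)
from .diffexpr import profile, round_report, summarize, tpm
from .hairpin import DEFAULT_FLANK_SETS, discover_novel
from .reads import read_fasta, process_libraries
from .targets import antisense_cognate_fraction, hotspot_stats, predict_targets

logger = logging.getLogger("mirnaome")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """All paths and thresholds of one pipeline run; YAML round-trippable."""

    fastq_a: str
    fastq_b: str
    transcript_fasta: str
    ncrna_fasta: str
    mature_fasta: str
    adapter_5p: str
    adapter_3p: str
    outdir: str
    min_len: int = 18
    max_len: int = 30
    min_count: int = 3
    max_mm: int = 4
    alpha: float = 0.01
    cutoff: float = 4.0
    flank_sets: list = field(default_factory=lambda: [list(f) for f in DEFAULT_FLANK_SETS])
    min_loop: int = 3
    wobble_weight: float = 1.0
    max_duplex_mm: int = 4
    max_asym_bulge: int = 2
    min_paired_frac: float = 0.60
    star_mm: int = 0
    bh: bool = False
    seed: int = 0

    def validate(self) -> None:
        for attr in ("fastq_a", "fastq_b", "transcript_fasta", "ncrna_fasta", "mature_fasta"):
            p = Path(getattr(self, attr))
            if not p.exists():
                raise FileNotFoundError(f"{attr}: {p} does not exist")
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("need 0 < min_len <= max_len")
        if self.min_count < 1 or self.max_mm < 0 or not 0 < self.alpha < 1:
            raise ValueError("thresholds out of documented range")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _fmt(x: float) -> str:
    return f"{round_report(x, 1):.1f}"


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns a dict of output paths and summary numbers.

    Fails atomically per stage: any error aborts with the stage name and no
    later outputs are written.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__,
                      "config": dataclasses.asdict(config), "stages": {}}

    def stage(name):
        logger.info("stage %s", name)
        return name

    try:
        name = stage("read_processing")
        table, stats = process_libraries(
            config.fastq_a, config.fastq_b, config.adapter_5p, config.adapter_3p,
            config.min_len, config.max_len, config.min_count)
        manifest["stages"][name] = stats
        logger.info("retained %d signatures (%d + %d reads)", len(table),
                    table.library_size_a, table.library_size_b)

        name = stage("annotation")
        transcript_ref = read_fasta(config.transcript_fasta)
        ncrna_ref = read_fasta(config.ncrna_fasta)
        mature_ref = read_fasta(config.mature_fasta)
        ncrna_asg = match_ncrna(table, ncrna_ref)
        known_asg = match_known_mirnas(table, mature_ref, config.max_mm)
        transcript_asg = match_transcripts(table, transcript_ref)
        manifest["stages"][name] = {
            "ncrna": len(ncrna_asg), "known": len(known_asg),
            "transcript_matched": len(transcript_asg)}

        name = stage("hairpin_discovery")
        consumed = set(ncrna_asg) | set(known_asg)
        candidate_seqs = sorted(s for s in transcript_asg if s not in consumed)
        calls = discover_novel(
            table, candidate_seqs, transcript_ref,
            flank_sets=[tuple(f) for f in config.flank_sets],
            min_loop=config.min_loop, wobble_weight=config.wobble_weight,
            max_duplex_mm=config.max_duplex_mm, max_asym_bulge=config.max_asym_bulge,
            min_paired_frac=config.min_paired_frac, star_mm=config.star_mm)
        accepted = [c for c in calls if c.accepted]
        manifest["stages"][name] = {
            "candidates": len(calls), "accepted": len(accepted),
            "no_star": sum(c.status == "no_star" for c in calls)}

        name = stage("categorize")
        novel_matures = {c.mature_seq for c in accepted}
        records = categorize(table, ncrna_asg, known_asg, transcript_asg, novel_matures)
        summary = category_summary(records)

        name = stage("differential")
        counts: dict[str, tuple[int, int]] = {}
        for sig, (rid, _mm, _fam) in known_asg.items():
            ca, cb = table.get(sig)
            pa, pb = counts.get(rid, (0, 0))
            counts[rid] = (pa + ca, pb + cb)
        novel_ids = {}
        for i, call in enumerate(sorted(accepted, key=lambda c: c.mature_seq), 1):
            nid = f"novel-{i:02d}"
            novel_ids[call.mature_seq] = nid
            counts[nid] = table.get(to_dna(call.mature_seq))
        diff = profile(counts, table.library_size_a, table.library_size_b,
                       alpha=config.alpha, bh=config.bh)
        manifest["stages"][name] = summarize(diff)

        name = stage("targets")
        mirna_seqs = {rid: seq for h, seq in mature_ref.items()
                      if (rid := h.split()[0]) in counts}
        for call in accepted:
            mirna_seqs[novel_ids[call.mature_seq]] = call.mature_seq
        hits = predict_targets(mirna_seqs, transcript_ref, config.cutoff)
        target_genes = sorted(set(hits["transcript_id"]))
        hotspots = hotspot_stats(target_genes, transcript_asg, table)
        cognate = antisense_cognate_fraction(transcript_asg, table)
        manifest["stages"][name] = {
            "target_hits": len(hits), "target_genes": len(target_genes)}
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - single abort point with stage context
        raise PipelineError(name, str(exc)) from exc

    # ---- write the bundle -------------------------------------------------
    paths = {}
    paths["annotation"] = outdir / "annotation.tsv"
    records.to_csv(paths["annotation"], sep="\t", index=False)
    paths["summary"] = outdir / "category_summary.tsv"
    summary.to_csv(paths["summary"], sep="\t", index=False, float_format="%.4f")
    paths["differential"] = outdir / "differential.tsv"
    diff.to_csv(paths["differential"], sep="\t", index=False)

    paths["novel"] = outdir / "novel_mirnas.tsv"
    with open(paths["novel"], "w") as fh:
        fh.write("mirna_id\tsequence\ttpm_a\ttpm_b\tfold_change\tprecursor_id\t"
                 "start\tend\tstar_found\tstatus\n")
        for call in calls:
            ca, cb = table.get(to_dna(call.mature_seq))
            t1 = tpm(ca, table.library_size_a)
            t2 = tpm(cb, table.library_size_b)
            if t1 == 0 and t2 == 0:
                fc = ""
            elif min(t1, t2) == 0:
                fc = "inf"
            else:
                fc = _fmt(max(t1, t2) / min(t1, t2))
            nid = novel_ids.get(call.mature_seq, "")
            fh.write(f"{nid}\t{call.mature_seq}\t{_fmt(t1)}\t{_fmt(t2)}\t{fc}\t"
                     f"{call.transcript_id}\t{call.precursor_start}\t"
                     f"{call.precursor_end}\t{'Yes' if call.accepted else 'No'}\t"
                     f"{call.status}\n")

    paths["structures"] = outdir / "precursor_structures.txt"
    with open(paths["structures"], "w") as fh:
        for call in calls:
            nid = novel_ids.get(call.mature_seq, call.mature_seq)
            fh.write(f">{nid} {call.transcript_id}:{call.precursor_start}-"
                     f"{call.precursor_end}({call.strand}) {call.status}\n")
            fh.write(call.fold.sequence + "\n")
            fh.write(call.fold.structure + "\n")

    paths["targets"] = outdir / "target_hits.tsv"
    hits.to_csv(paths["targets"], sep="\t", index=False)
    paths["hotspots"] = outdir / "hotspot_summary.tsv"
    with open(paths["hotspots"], "w") as fh:
        keys = list(hotspots["A"].as_dict())
        fh.write("library\t" + "\t".join(keys) + "\n")
        for lib in ("A", "B"):
            d = hotspots[lib].as_dict()
            fh.write(lib + "\t" + "\t".join(
                f"{d[k]:.1f}" if isinstance(d[k], float) else str(d[k]) for k in keys) + "\n")
        fh.write("# antisense_cognate_fraction\tA={:.4f}\tB={:.4f}\n".format(
            cognate["A"], cognate["B"]))

    paths["manifest"] = outdir / "run_manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {"paths": {k: str(v) for k, v in paths.items()},
            "manifest": manifest,
            "table": table, "records": records, "summary": summary,
            "calls": calls, "diff": diff, "hotspots": hotspots}


def report(outdir: str | Path) -> str:
    """Human-readable summary of a completed run's output bundle."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "run_manifest.json").read_text())
    lines = [f"mirnaome run summary (v{manifest['version']})", ""]
    st = manifest["stages"]
    rp = st.get("read_processing", {})
    lines.append(f"reads: {rp.get('raw_reads_a', 0)} (A) / {rp.get('raw_reads_b', 0)} (B); "
                 f"retained {rp.get('retained_reads_a', 0)} / {rp.get('retained_reads_b', 0)} "
                 f"in {rp.get('signatures', 0)} signatures")
    import pandas as pd
    summary = pd.read_csv(outdir / "category_summary.tsv", sep="\t")
    lines.append("")
    lines.append("category\tdistinct_a(%)\tdistinct_b(%)")
    for _, row in summary.iterrows():
        lines.append(f"{row['category']}\t{int(row['distinct_a'])} "
                     f"({row['pct_distinct_a']:.2f}%)\t{int(row['distinct_b'])} "
                     f"({row['pct_distinct_b']:.2f}%)")
    hd = st.get("hairpin_discovery", {})
    lines.append("")
    lines.append(f"novel miRNA calls: {hd.get('accepted', 0)} accepted of "
                 f"{hd.get('candidates', 0)} candidate matures "
                 f"({hd.get('no_star', 0)} rejected for missing miRNA*)")
    dd = st.get("differential", {})
    lines.append(f"differential: {dd.get('n_significant', 0)} of {dd.get('n_genes', 0)} "
                 f"miRNAs significant; {dd.get('n_two_fold', 0)} with >2-fold change")
    tg = st.get("targets", {})
    lines.append(f"targets: {tg.get('target_hits', 0)} sites on "
                 f"{tg.get('target_genes', 0)} genes")
    return "\n".join(lines) + "\n"
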