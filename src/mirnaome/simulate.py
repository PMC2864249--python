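"""Synthetic two-condition small-RNA study generator with known ground truth.

Emulates a two-library (wild type vs mutant) plant small-RNA sequencing
design: reference transcripts with planted miRNA hairpin genes, a
non-coding-RNA catalogue (rRNA/tRNA/snRNA/snoRNA), a mature-miRNA
catalogue that contains the "known" planted matures and withholds the
"novel" ones, and two FASTQ read libraries in which each planted gene is
sampled at a configured abundance (reads per million) with a multiplicative
condition effect, plus background fragments from the references and a small
rate of junk reads lacking adapters.  Background signature lengths follow a
18-30 nt distribution with a 24-nt mode, the hallmark of plant small-RNA
libraries where 24-nt heterochromatic siRNAs dominate.

Planted hairpins are built analytically, never by folding: the precursor is
a perfect stem (lower stem + mature, paired to its reverse complement)
closed by a short non-self-pairing loop, and the miRNA* is the duplex
partner of the mature with canonical 2-nt 3' overhangs on both strands.
Ground truth (the manifest) therefore never depends on the folding engine
under test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seq import revcomp, to_dna, to_rna


class SimulationError(RuntimeError):
    """Raised when a planted gene cannot be constructed within the retry budget."""


#: Background signature length weights (18-30 nt): ~95% of mass in 21-24 nt
#: with the 24-nt class as the major peak, as in plant small-RNA libraries.
DEFAULT_LENGTH_WEIGHTS: dict[int, float] = {
    18: 0.003, 19: 0.003, 20: 0.010,
    21: 0.110, 22: 0.140, 23: 0.130, 24: 0.570,
    25: 0.010, 26: 0.007, 27: 0.006, 28: 0.005, 29: 0.003, 30: 0.003,
}

# Illumina-style small-RNA ligation adapters (any >=7 nt sequences work).
DEFAULT_ADAPTER_5P = "GTTCAGAGTTCTACAGTCCGACGATC"
DEFAULT_ADAPTER_3P = "TGGAATTCTCGGGTGCCAAGG"

_NT = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedMiRNA:
    """Ground truth for one planted miRNA gene.

    ``mature_start`` is the 0-based offset of the mature within the
    precursor; ``precursor_start`` the offset of the precursor within the
    host transcript.  ``base_abundance`` is the expected reads per million
    in condition A; condition B multiplies it by ``fold_effect``
    (``fold_effect == 1`` marks a null, non-differential gene).
    ``star_fraction`` is the fraction of the gene's reads drawn from the
    miRNA* arm.  Sequences are stored as RNA.
    """

    id: str
    mature_seq: str
    star_seq: str
    precursor_seq: str
    host_transcript: str
    mature_start: int
    base_abundance: float
    fold_effect: float
    star_fraction: float
    known: bool = False
    precursor_start: int = 0

    @property
    def star_start(self) -> int:
        """0-based offset of the star within the precursor."""
        i = self.precursor_seq.find(self.star_seq)
        if i < 0:
            raise ValueError(f"star not in precursor for {self.id}")
        return i


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study; fixed seed gives bit-identical output."""

    n_transcripts: int = 300
    transcript_len_range: tuple[int, int] = (800, 2500)
    n_mirnas: int = 20
    n_known: int = 10
    n_noncoding_refs: int = 12
    library_sizes: tuple[int, int] = (200_000, 200_000)
    length_mode_weights: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS))
    adapter_5p: str = DEFAULT_ADAPTER_5P
    adapter_3p: str = DEFAULT_ADAPTER_3P
    seed: int = 0
    # gene-model knobs
    mature_len_range: tuple[int, int] = (20, 22)
    abundance_range: tuple[float, float] = (100.0, 800.0)
    fold_effects: tuple[float, ...] = (1.0, 4.0, 0.25)
    star_fraction: float = 0.15
    junk_rate: float = 0.01
    stem_flank: int = 22
    loop_linker: str = "AACAAACA"  # A/C only: cannot pair with itself

    def validate(self) -> None:
        if self.n_transcripts <= 0 or self.n_noncoding_refs <= 0:
            raise ValueError("reference counts must be positive")
        if not (0 <= self.n_known <= self.n_mirnas):
            raise ValueError("n_known must be within [0, n_mirnas]")
        if min(self.library_sizes) <= 0:
            raise ValueError("library sizes must be positive")
        total = sum(self.length_mode_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"length_mode_weights must sum to 1 (got {total})")
        if any(not 18 <= k <= 30 for k in self.length_mode_weights):
            raise ValueError("length weights must cover 18-30 nt only")
        if len(self.adapter_5p) < 7 or len(self.adapter_3p) < 7:
            raise ValueError("adapters must be at least 7 nt")
        if not 0 <= self.star_fraction < 1:
            raise ValueError("star_fraction must be in [0, 1)")
        if any(f <= 0 for f in self.fold_effects):
            raise ValueError("fold effects must be positive")


@dataclass
class References:
    """The three reference FASTAs plus the ground-truth gene list."""

    transcripts: dict[str, str]
    ncrna: dict[str, str]
    mature_catalog: dict[str, str]  # id -> RNA sequence (known matures + decoys)
    planted: list[PlantedMiRNA]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "transcripts": outdir / "transcripts.fasta",
            "ncrna": outdir / "ncrna.fasta",
            "mature": outdir / "mature_mirnas.fasta",
            "manifest": outdir / "ground_truth.tsv",
        }
        _write_fasta(paths["transcripts"], self.transcripts)
        _write_fasta(paths["ncrna"], self.ncrna)
        _write_fasta(paths["mature"], self.mature_catalog)
        write_manifest(paths["manifest"], self.planted)
        return paths


def _write_fasta(path: Path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_manifest(path: str | Path, planted: list[PlantedMiRNA]) -> None:
    cols = ("id", "mature_seq", "star_seq", "precursor_seq", "host_transcript",
            "mature_start", "precursor_start", "base_abundance", "fold_effect",
            "star_fraction", "known")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for g in planted:
            fh.write("\t".join(str(getattr(g, c)) for c in cols) + "\n")


def read_manifest(path: str | Path) -> list[PlantedMiRNA]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            rec = dict(zip(header, line.rstrip("\n").split("\t")))
            out.append(PlantedMiRNA(
                id=rec["id"], mature_seq=rec["mature_seq"], star_seq=rec["star_seq"],
                precursor_seq=rec["precursor_seq"], host_transcript=rec["host_transcript"],
                mature_start=int(rec["mature_start"]), precursor_start=int(rec["precursor_start"]),
                base_abundance=float(rec["base_abundance"]), fold_effect=float(rec["fold_effect"]),
                star_fraction=float(rec["star_fraction"]), known=rec["known"] == "True",
            ))
    return out


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[rng.integers(0, 4, n)])


def make_hairpin(mature_dna: str, stem_flank: int, linker: str,
                 rng: np.random.Generator) -> tuple[str, str, int]:
    """Build (precursor_dna, star_dna, mature_start) around a mature sequence.

    Layout: ``B + M + linker + revcomp(M[:-2]) + revcomp(B)`` with B a random
    lower stem.  The stem ``B + M[:-2]`` pairs perfectly with its reverse
    complement; the terminal loop is the mature's last two nt plus the
    linker.  The star is the duplex partner of the mature with 2-nt 3'
    overhangs on both strands: ``revcomp(M[:-2]) + revcomp(B[-2:])``.
    """
    b = _random_seq(rng, stem_flank)
    precursor = b + mature_dna + linker + revcomp(b + mature_dna[:-2])
    star = revcomp(mature_dna[:-2]) + revcomp(b)[:2]
    return precursor, star, stem_flank


def _min_sliding_distance(a: str, b: str) -> int:
    """Naive min-over-offsets ungapped distance; overhangs count as mismatches."""
    best = len(a) + len(b)
    for off in range(-(len(b) - 1), len(a)):
        overlap = 0
        mm = 0
        for j, cb in enumerate(b):
            i = off + j
            if 0 <= i < len(a):
                overlap += 1
                mm += a[i] != cb
        if overlap:
            best = min(best, mm + (len(a) - overlap) + (len(b) - overlap))
    return best


_NC_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA")


def build_references(config: SimulationConfig) -> References:
    """Generate transcripts, ncRNA and mature-miRNA references plus ground truth.

    Each planted gene's precursor is embedded once in a distinct transcript;
    the mature catalogue contains the known planted matures (with miRBase-like
    family headers) plus decoys, and withholds the novel planted matures.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.n_mirnas > config.n_transcripts:
        raise ValueError("need at least one transcript per planted miRNA")

    lo, hi = config.transcript_len_range
    transcripts = {f"TC{1000 + i}": _random_seq(rng, int(rng.integers(lo, hi + 1)))
                   for i in range(config.n_transcripts)}
    t_ids = list(transcripts)

    ncrna = {}
    for i in range(config.n_noncoding_refs):
        cls = _NC_CLASSES[i % len(_NC_CLASSES)]
        ncrna[f"NC{2000 + i} class={cls}"] = _random_seq(rng, int(rng.integers(80, 300)))

    planted: list[PlantedMiRNA] = []
    host_ids = list(rng.permutation(t_ids))[: config.n_mirnas]
    all_matures: list[str] = []
    catalog: dict[str, str] = {}
    for gi in range(config.n_mirnas):
        known = gi < config.n_known
        gid = (f"syn-miR{200 + gi}" if known else f"syn-novel-{gi - config.n_known + 1:02d}")
        for attempt in range(50):
            mlen = int(rng.integers(config.mature_len_range[0], config.mature_len_range[1] + 1))
            mature = _random_seq(rng, mlen)
            precursor, star, m_start = make_hairpin(mature, config.stem_flank, config.loop_linker, rng)
            host = host_ids[gi]
            tseq = transcripts[host]
            if len(tseq) < len(precursor) + 40:
                continue
            pos = int(rng.integers(20, len(tseq) - len(precursor) - 20))
            new_t = tseq[:pos] + precursor + tseq[pos + len(precursor):]
            everywhere = "".join(transcripts[t] if t != host else new_t for t in t_ids)
            if everywhere.count(mature) != 1 or precursor.count(mature) != 1:
                continue
            if any(_min_sliding_distance(mature, m) <= 6 for m in all_matures):
                continue
            transcripts[host] = new_t
            log_lo, log_hi = math.log(config.abundance_range[0]), math.log(config.abundance_range[1])
            planted.append(PlantedMiRNA(
                id=gid,
                mature_seq=to_rna(mature),
                star_seq=to_rna(star),
                precursor_seq=to_rna(precursor),
                host_transcript=host,
                mature_start=m_start,
                precursor_start=pos,
                base_abundance=float(np.exp(rng.uniform(log_lo, log_hi))),
                fold_effect=float(config.fold_effects[gi % len(config.fold_effects)]),
                star_fraction=config.star_fraction,
                known=known,
            ))
            all_matures.append(mature)
            if known:
                catalog[f"ath-{gid.split('-', 1)[1]}"] = to_rna(mature)
            break
        else:
            raise SimulationError(f"could not construct planted gene {gid}")

    # decoy catalogue entries: plausible matures never present in the libraries
    for d in range(5):
        for attempt in range(50):
            decoy = _random_seq(rng, 21)
            if all(_min_sliding_distance(decoy, m) > 6 for m in all_matures):
                catalog[f"ath-miR{900 + d}"] = to_rna(decoy)
                all_matures.append(decoy)
                break

    return References(transcripts=transcripts, ncrna=ncrna,
                      mature_catalog=catalog, planted=planted)


def _planted_pool(planted: list[PlantedMiRNA]) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Insert pool (DNA) and per-million weights for the two conditions."""
    seqs: list[str] = []
    wa: list[float] = []
    wb: list[float] = []
    for g in planted:
        m = to_dna(g.mature_seq)
        s = to_dna(g.star_seq)
        seqs.append(m)
        wa.append(g.base_abundance * (1 - g.star_fraction))
        wb.append(g.base_abundance * (1 - g.star_fraction) * g.fold_effect)
        seqs.append(s)
        wa.append(g.base_abundance * g.star_fraction)
        wb.append(g.base_abundance * g.star_fraction * g.fold_effect)
    return seqs, np.array(wa), np.array(wb)


def simulate_tag_counts(
    genes: list[tuple[str, float, float]],
    library_sizes: tuple[int, int],
    rng: np.random.Generator,
) -> tuple[dict[str, tuple[int, int]], int, int]:
    """Counts-level simulation of per-gene tag counts in two libraries.

    ``genes`` is a list of ``(id, base_abundance_per_million, fold_effect)``;
    the remaining probability mass is an aggregate background category.
    Returns ``({id: (x1, x2)}, N1, N2)``.  This is the sampling model of the
    full read simulator with read construction skipped; it is the natural
    input for calibration studies of the differential test.
    """
    ids = [g[0] for g in genes]
    wa = np.array([g[1] for g in genes], dtype=float)
    wb = np.array([g[1] * g[2] for g in genes], dtype=float)
    for w in (wa, wb):
        if w.sum() >= 1e6:
            raise ValueError("planted abundance exceeds library capacity")
    n1, n2 = library_sizes
    xa = rng.multinomial(n1, np.append(wa, 1e6 - wa.sum()) / 1e6)
    xb = rng.multinomial(n2, np.append(wb, 1e6 - wb.sum()) / 1e6)
    counts = {gid: (int(xa[i]), int(xb[i])) for i, gid in enumerate(ids)}
    return counts, n1, n2


def _background_inserts(refs: References, n: int, weights: dict[int, float],
                        rng: np.random.Generator) -> list[str]:
    """Sample n background inserts uniformly over reference positions, both strands."""
    pool = list(refs.transcripts.items()) + [(k, v) for k, v in refs.ncrna.items()]
    names = [p[0] for p in pool]
    seqs = [p[1] for p in pool]
    lens = np.array([len(s) for s in seqs], dtype=float)
    ridx = rng.choice(len(pool), size=n, p=lens / lens.sum())
    klens = np.array(sorted(weights))
    kl = rng.choice(klens, size=n, p=np.array([weights[k] for k in klens]))
    strands = rng.integers(0, 2, size=n)
    out = []
    for i in range(n):
        s = seqs[ridx[i]]
        l = int(kl[i])
        if len(s) <= l:
            frag = s
        else:
            start = int(rng.integers(0, len(s) - l + 1))
            frag = s[start:start + l]
        out.append(frag if strands[i] == 0 else revcomp(frag))
    return out


def simulate_inserts(refs: References, config: SimulationConfig,
                     rng: np.random.Generator, condition: str) -> tuple[list[str], list[str]]:
    """Draw one library's inserts; returns (inserts, junk_reads).

    Multinomial sampling to the configured library size over planted matures
    and stars (per-million weights, condition B multiplied by fold_effect),
    an aggregate background category expanded from reference fragments, and
    junk reads carrying no adapters.
    """
    lib_size = config.library_sizes[0 if condition == "A" else 1]
    seqs, wa, wb = _planted_pool(refs.planted)
    w = wa if condition == "A" else wb
    junk_w = config.junk_rate * 1e6
    bg_w = 1e6 - w.sum() - junk_w
    if bg_w <= 0:
        raise ValueError("planted abundance + junk exceeds library capacity")
    probs = np.append(w, [bg_w, junk_w]) / 1e6
    counts = rng.multinomial(lib_size, probs)
    inserts: list[str] = []
    for seq, c in zip(seqs, counts[:-2]):
        inserts.extend([seq] * int(c))
    inserts.extend(_background_inserts(refs, int(counts[-2]), config.length_mode_weights, rng))
    junk = [_random_seq(rng, 40) for _ in range(int(counts[-1]))]
    return inserts, junk


def simulate_libraries(refs: References, config: SimulationConfig,
                       outdir: str | Path) -> tuple[Path, Path]:
    """Write the two FASTQ libraries (Phred+33, dummy quality 'I').

    Reads are ``adapter_5p + insert + adapter_3p``; junk reads are plain
    random sequence rejected at trimming.  Fixed seed gives byte-identical
    files.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 1)
    paths = []
    for cond in ("A", "B"):
        inserts, junk = simulate_inserts(refs, config, rng, cond)
        reads = [config.adapter_5p + ins + config.adapter_3p for ins in inserts] + junk
        order = rng.permutation(len(reads))
        path = outdir / f"library_{cond}.fastq"
        with open(path, "w") as fh:
            for n, i in enumerate(order):
                r = reads[i]
                fh.write(f"@{cond}_{n:07d}\n{r}\n+\n{'I' * len(r)}\n")
        paths.append(path)
    return paths[0], paths[1]
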