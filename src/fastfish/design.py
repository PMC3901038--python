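"""Design of intrinsically unstructured three-base probe/target pairs.

RNA targets drawn from the {A, U, C} alphabet avoid guanine — the base most
potent in self-pairing (G:C Watson–Crick and G·U wobble) — and are therefore
largely free of secondary structure, which lets a complementary {A, T, G} DNA
probe anneal at near diffusion-limited rates (~1e7 /M/s).  Specificity is
preserved by keeping only candidates whose LZ76 complexity clears a floor, so
repetitive sequences never make it into the ranked output.

This module generates GC-balanced random k-mers over a chosen alphabet,
scores them (GC fraction, G count, LZ76 complexity, optional externally
computed self-folding energy) and emits ranked target/probe pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .complexity import lz_complexity

__all__ = [
    "AlphabetSpec",
    "OligoRecord",
    "DesignConfig",
    "RNA_AUC",
    "DNA_ATG",
    "RNA_AUGC",
    "DNA_ATGC",
    "generate_random_kmers",
    "residue_count",
    "gc_fraction",
    "reverse_complement_probe",
    "pairing_proxy",
    "load_fold_energies",
    "design_probes",
]

logger = logging.getLogger(__name__)

_RNA_LETTERS = set("ACGU")
_DNA_LETTERS = set("ACGT")


@dataclass(frozen=True)
class AlphabetSpec:
    """A restricted nucleotide alphabet (3 or 4 letters, RNA or DNA)."""

    letters: tuple[str, ...]
    kind: str  # "RNA" or "DNA"

    def __post_init__(self):
        if self.kind not in ("RNA", "DNA"):
            raise ValueError(f"kind must be 'RNA' or 'DNA', got {self.kind!r}")
        allowed = _RNA_LETTERS if self.kind == "RNA" else _DNA_LETTERS
        if len(set(self.letters)) != len(self.letters):
            raise ValueError("alphabet letters must be unique")
        if not set(self.letters) <= allowed:
            raise ValueError(
                f"letters {self.letters} not a subset of {sorted(allowed)} for {self.kind}"
            )
        if not 3 <= len(self.letters) <= 4:
            raise ValueError("alphabet must have 3 or 4 letters")


RNA_AUC = AlphabetSpec(("A", "U", "C"), "RNA")
RNA_AUG = AlphabetSpec(("A", "U", "G"), "RNA")
RNA_CAG = AlphabetSpec(("C", "A", "G"), "RNA")
RNA_CUG = AlphabetSpec(("C", "U", "G"), "RNA")
RNA_AUGC = AlphabetSpec(("A", "U", "G", "C"), "RNA")
DNA_ATC = AlphabetSpec(("A", "T", "C"), "DNA")
DNA_ATG = AlphabetSpec(("A", "T", "G"), "DNA")
DNA_CAG = AlphabetSpec(("C", "A", "G"), "DNA")
DNA_CTG = AlphabetSpec(("C", "T", "G"), "DNA")
DNA_ATGC = AlphabetSpec(("A", "T", "G", "C"), "DNA")


def normalize_sequence(sequence: str, kind: str | None = None) -> str:
    """Uppercase *sequence*; interconvert U/T when *kind* is given."""
    seq = sequence.upper()
    if kind == "RNA":
        seq = seq.replace("T", "U")
    elif kind == "DNA":
        seq = seq.replace("U", "T")
    return seq


def _validate(sequence: str, allowed: set[str]) -> str:
    bad = set(sequence) - allowed
    if bad:
        raise ValueError(f"invalid symbols {sorted(bad)} in sequence {sequence!r}")
    return sequence


@dataclass
class OligoRecord:
    """A scored candidate oligonucleotide."""

    sequence: str
    gc_fraction: float
    g_count: int
    lz_complexity: int
    fold_energy: float | None = None  # kcal/mol, from an external folding tool

    @classmethod
    def from_sequence(cls, sequence: str, kind: str | None = None) -> "OligoRecord":
        seq = normalize_sequence(sequence, kind)
        _validate(seq, _RNA_LETTERS | _DNA_LETTERS)
        return cls(
            sequence=seq,
            gc_fraction=gc_fraction(seq),
            g_count=residue_count(seq, "G"),
            lz_complexity=lz_complexity(seq),
        )


@dataclass
class DesignConfig:
    """Parameters of a probe-design run.

    ``gc_range`` is inclusive on both ends; ``complexity_min`` keeps only
    candidates at or above the complexity floor (the default 9 matches or
    exceeds the mean complexity of natural exon 19-mers).
    """

    k: int = 19
    gc_range: tuple[float, float] = (0.4, 0.6)
    complexity_min: int = 9
    n_samples: int = 10_000
    seed: int = 0
    fold_energy_min: float | None = None
    target_alphabet: AlphabetSpec = field(default_factory=lambda: RNA_AUC)
    probe_alphabet: AlphabetSpec = field(default_factory=lambda: DNA_ATG)
    context_pairing_max: int = 4  # warn when target pairs this much with flanks

    def __post_init__(self):
        lo, hi = self.gc_range
        if not 0 <= lo <= hi <= 1:
            raise ValueError(f"invalid gc_range {self.gc_range}")
        if self.k < 1 or self.n_samples < 1:
            raise ValueError("k and n_samples must be >= 1")


def residue_count(sequence: str, base: str) -> int:
    """Exact count of *base* in *sequence* (symbols validated)."""
    _validate(sequence.upper(), _RNA_LETTERS | _DNA_LETTERS)
    return sequence.upper().count(base.upper())


def gc_fraction(sequence: str) -> float:
    """(#G + #C) / length of *sequence*."""
    seq = sequence.upper()
    _validate(seq, _RNA_LETTERS | _DNA_LETTERS)
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def _gc_count_window(k: int, gc_range: tuple[float, float]) -> tuple[int, int]:
    """Integer GC-count window implied by an inclusive GC-fraction range."""
    lo, hi = gc_range
    c_lo = math.ceil(lo * k - 1e-9)
    c_hi = math.floor(hi * k + 1e-9)
    return c_lo, c_hi


def generate_random_kmers(
    alphabet: AlphabetSpec,
    k: int = 19,
    n: int = 10_000,
    gc_range: tuple[float, float] = (0.4, 0.6),
    seed: int = 0,
) -> tuple[list[OligoRecord], float]:
    """Sample *n* distinct random k-mers and keep the GC-balanced ones.

    Draws are uniform over ``alphabet**k`` without replacement (distinct
    integer codes, duplicates rejected by hashing).  A sequence is retained
    when its GC fraction lies inclusively inside *gc_range*; for a three-base
    {A,U,C} alphabet the GC fraction is simply the C fraction.

    Returns
    -------
    (records, yield_fraction)
        The retained :class:`OligoRecord` list and retained/n.
    """
    c_lo, c_hi = _gc_count_window(k, gc_range)
    gc_letters = [i for i, letter in enumerate(alphabet.letters) if letter in "GC"]
    max_gc = k if gc_letters else 0
    if c_lo > c_hi or c_lo > max_gc:
        raise ValueError(
            f"gc_range {gc_range} admits no integer GC count for k={k} over "
            f"{alphabet.letters}; achievable counts are 0..{max_gc}, the range "
            f"requires a count in [{c_lo}, {c_hi}]"
        )
    base = len(alphabet.letters)
    space = base**k
    if n > space:
        raise ValueError(f"cannot draw {n} distinct sequences from a space of {space}")

    rng = np.random.default_rng(seed)
    seen: set[int] = set()
    codes: list[int] = []
    while len(codes) < n:
        batch = rng.integers(0, space, size=max(1024, n - len(codes)), dtype=np.int64)
        for code in batch:
            code = int(code)
            if code not in seen:
                seen.add(code)
                codes.append(code)
                if len(codes) == n:
                    break

    gc_idx = set(gc_letters)
    records: list[OligoRecord] = []
    letters = alphabet.letters
    for code in codes:
        digits = []
        x = code
        for _ in range(k):
            digits.append(x % base)
            x //= base
        gc = sum(1 for d in digits if d in gc_idx)
        if c_lo <= gc <= c_hi:
            seq = "".join(letters[d] for d in digits)
            records.append(
                OligoRecord(
                    sequence=seq,
                    gc_fraction=gc / k,
                    g_count=seq.count("G"),
                    lz_complexity=lz_complexity(seq),
                )
            )
    return records, len(records) / n


def reverse_complement_probe(rna_target: str) -> str:
    """DNA probe complementary to an RNA target (reverse complement).

    A pure three-base {A,U,C} target maps onto a pure {A,T,G} probe, so both
    strands of the pair stay intrinsically unstructured.
    """
    seq = normalize_sequence(rna_target, "RNA")
    _validate(seq, _RNA_LETTERS)
    return str(Seq(seq).reverse_complement()).replace("U", "T")


def target_from_probe(dna_probe: str) -> str:
    """Inverse of :func:`reverse_complement_probe`."""
    seq = normalize_sequence(dna_probe, "DNA")
    _validate(seq, _DNA_LETTERS)
    return str(Seq(seq).reverse_complement()).replace("T", "U")


_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


def pairing_proxy(sequence: str, min_loop: int = 3) -> int:
    """Maximum number of nested self base pairs (Nussinov dynamic program).

    Counts Watson–Crick plus G·U wobble pairs with hairpin loops of at least
    *min_loop* unpaired bases.  This is a structure-propensity score, not a
    thermodynamic model: higher values flag sequences more likely to fold on
    themselves and hybridize slowly.
    """
    seq = normalize_sequence(sequence, "RNA")
    if not seq:
        raise ValueError("empty sequence")
    _validate(seq, _RNA_LETTERS)
    n = len(seq)
    dp = np.zeros((n, n), dtype=int)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1, j - 1] + 1 if (seq[i], seq[j]) in _PAIRS else 0
            best = max(best, dp[i + 1, j], dp[i, j - 1])
            for t in range(i + 1, j):
                best = max(best, dp[i, t] + dp[t + 1, j])
            dp[i, j] = best
    return int(dp[0, n - 1])


def load_fold_energies(table, oligos: list[OligoRecord]) -> list[str]:
    """Attach externally computed self-folding energies to oligo records.

    Parameters
    ----------
    table:
        Path to a two-column TSV (sequence, kcal/mol) produced by an external
        folding tool, or an iterable of ``(sequence, energy)`` pairs.
    oligos:
        Records to annotate in place (matched on normalized sequence).

    Returns
    -------
    list of sequences present in the table but matching no record.
    """
    if isinstance(table, (str, Path)):
        rows = []
        with open(table) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"malformed row at line {lineno}: {line!r}")
                try:
                    rows.append((parts[0], float(parts[1])))
                except ValueError as exc:
                    raise ValueError(f"malformed row at line {lineno}: {line!r}") from exc
    else:
        rows = [(s, float(e)) for s, e in table]

    energies: dict[str, float] = {}
    for seq, energy in rows:
        key = seq.upper()
        if key in energies and energies[key] != energy:
            raise ValueError(f"conflicting fold energies for sequence {seq!r}")
        energies[key] = energy

    by_seq = {rec.sequence.upper(): rec for rec in oligos}
    unmatched = []
    for seq, energy in energies.items():
        rec = by_seq.get(seq)
        if rec is None:
            unmatched.append(seq)
        else:
            rec.fold_energy = energy
    return unmatched


def design_probes(
    config: DesignConfig,
    context: str | None = None,
    fold_energies=None,
) -> list[tuple[OligoRecord, OligoRecord]]:
    """Generate ranked (target, probe) candidate pairs.

    Targets are sampled over ``config.target_alphabet``, filtered on GC
    fraction and on ``complexity_min`` (and on ``fold_energy_min`` when
    energies are supplied); each probe is the reverse-complement DNA of its
    target.  When *context* (flanking transcript sequence) is given, a pair
    is flagged with a warning string in ``probe.sequence``-order when the
    target window pairs extensively with the flanks (a stand-in for a full
    secondary-structure check of the transcript).

    Ranking: complexity descending, then fold energy descending (unstructured
    first), then lexicographic for determinism.
    """
    records, _ = generate_random_kmers(
        config.target_alphabet, config.k, config.n_samples, config.gc_range, config.seed
    )
    if fold_energies is not None:
        load_fold_energies(fold_energies, records)

    kept = [r for r in records if r.lz_complexity >= config.complexity_min]
    if config.fold_energy_min is not None:
        kept = [
            r
            for r in kept
            if r.fold_energy is not None and r.fold_energy >= config.fold_energy_min
        ]
    if not kept:
        logger.info("no candidates survived the design filters")
        return []

    kept.sort(
        key=lambda r: (
            -r.lz_complexity,
            -(r.fold_energy if r.fold_energy is not None else -math.inf),
            r.sequence,
        )
    )
    pairs = []
    for rec in kept:
        probe = OligoRecord.from_sequence(reverse_complement_probe(rec.sequence), "DNA")
        probe.fold_energy = None
        if context is not None:
            ctx = normalize_sequence(context, "RNA")
            score = pairing_proxy(rec.sequence + ctx)
            baseline = pairing_proxy(ctx) if len(ctx) > 4 else 0
            if score - baseline > config.context_pairing_max:
                logger.warning(
                    "target %s pairs with flanking context (score %d over baseline %d)",
                    rec.sequence,
                    score,
                    baseline,
                )
        pairs.append((rec, probe))
    return pairs
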