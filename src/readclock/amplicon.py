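"""Per-read methylation calling against bisulfite amplicon references.

Bisulfite conversion turns unmethylated cytosine into uracil (read as T)
while 5-methylcytosine stays C. For an amplicon product anchored at the
reference start, each CpG cytosine therefore reads C if the molecule was
methylated there and T if not; cytosines outside CpG context are almost
never methylated in mammalian blood, so the fraction of them read as T is
a per-read measure of conversion completeness.

Calling here is alignment-free: amplicon reads are fixed-layout, so bases
are compared positionally and a mismatch fraction over non-convertible
positions catches gross failures (indels, off-target products). Reads
from the bottom strand appear, after reverse complement, with conversion
in G->A space; they are detected by comparing the read prefix against the
converted reference in both orientations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AmpliconSpec",
    "ReadCall",
    "ReadPatternTable",
    "call_read",
    "call_reads",
    "build_pattern_table",
    "beta_from_patterns",
    "neighbor_correlation",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AmpliconSpec:
    """An amplicon reference with indexed CpG positions.

    Parameters
    ----------
    name
        Amplicon identifier (e.g. gene name).
    reference_seq
        Uppercase genomic top-strand sequence, unconverted.
    cpg_positions
        0-based offsets of the C of each CG dinucleotide, strictly
        increasing; the coordinate frame for every pattern downstream.
    max_mismatch_frac
        QC ceiling on the fraction of non-convertible positions that
        disagree with the reference.
    min_conversion
        QC floor on the fraction of non-CpG cytosines read as converted.
    anchor_len
        Prefix length used to detect read orientation.
    """

    name: str
    reference_seq: str
    cpg_positions: tuple[int, ...]
    max_mismatch_frac: float = 0.1
    min_conversion: float = 0.9
    anchor_len: int = 15

    def __post_init__(self) -> None:
        object.__setattr__(self, "cpg_positions", tuple(self.cpg_positions))
        object.__setattr__(self, "reference_seq", self.reference_seq.upper())
        if not self.cpg_positions:
            raise ValueError(f"{self.name}: amplicon must contain at least one CpG")
        prev = -1
        for p in self.cpg_positions:
            if p <= prev:
                raise ValueError(f"{self.name}: cpg_positions must be strictly increasing")
            prev = p
            if p + 1 >= len(self.reference_seq):
                raise ValueError(f"{self.name}: CpG offset {p} outside reference")
            if self.reference_seq[p : p + 2] != "CG":
                raise ValueError(
                    f"{self.name}: reference does not carry CG at offset {p} "
                    f"(found {self.reference_seq[p:p + 2]!r})"
                )
        if not (0.0 <= self.max_mismatch_frac <= 1.0):
            raise ValueError("max_mismatch_frac must be in [0, 1]")
        if not (0.0 <= self.min_conversion <= 1.0):
            raise ValueError("min_conversion must be in [0, 1]")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)

    def cpg_ids(self) -> list[str]:
        """Column labels '<amplicon>:<index>' in CpG order."""
        return [f"{self.name}:{i}" for i in range(self.n_cpgs)]

    def converted_reference(self, methylated: bool = True) -> str:
        """Top-strand reference after bisulfite conversion.

        Non-CpG Cs always become T; CpG Cs stay C when ``methylated``.
        """
        cpg = set(self.cpg_positions)
        return "".join(
            b if b != "C" or (i in cpg and methylated) else "T"
            for i, b in enumerate(self.reference_seq)
        )


@dataclass(frozen=True)
class ReadCall:
    """Binary methylation call for one read.

    ``pattern`` holds one entry per CpG of the spec: 1 methylated,
    0 unmethylated, -1 missing (read too short or unexpected base).
    """

    pattern: tuple[int, ...]
    conversion_rate: float
    mismatch_frac: float
    passed_qc: bool
    qc_reason: str = ""
    strand: str = "top"

    def pattern_string(self) -> str:
        return "".join("?" if x < 0 else str(x) for x in self.pattern)


def call_read(read_seq: str, spec: AmpliconSpec, strand: str = "auto") -> ReadCall:
    """Call one read against the amplicon.

    ``strand='auto'`` tries the top-strand C/T rule and the bottom-strand
    G/A rule (on the reverse-complemented read) and keeps whichever gives
    the lower mismatch fraction. Trailing CpGs beyond the read end are
    missing, not an error; an empty read fails QC outright.
    """
    read_seq = read_seq.upper()
    if not read_seq:
        n = spec.n_cpgs
        return ReadCall((-1,) * n, 0.0, 1.0, False, qc_reason="empty read")
    if strand == "auto":
        top = _call_oriented(read_seq, spec, "top")
        bottom = _call_oriented(reverse_complement(read_seq), spec, "bottom")
        return top if top.mismatch_frac <= bottom.mismatch_frac else bottom
    if strand == "top":
        return _call_oriented(read_seq, spec, "top")
    if strand == "bottom":
        return _call_oriented(reverse_complement(read_seq), spec, "bottom")
    raise ValueError(f"strand must be 'top', 'bottom' or 'auto', got {strand!r}")


def _call_oriented(seq: str, spec: AmpliconSpec, strand: str) -> ReadCall:
    """Call a read already in top-strand coordinates.

    For ``strand='bottom'`` the convertible base is the complement: the
    CpG is read at its G (G methylated, A converted) and conversion QC
    runs over non-CpG reference Gs.
    """
    ref = spec.reference_seq
    L = min(len(seq), len(ref))
    read = np.frombuffer(seq[:L].encode(), dtype="S1")
    refarr = np.frombuffer(ref.encode(), dtype="S1")[:L]

    if strand == "top":
        conv_from, conv_to = b"C", b"T"
        cpg_obs = np.asarray(spec.cpg_positions, dtype=int)
    else:
        conv_from, conv_to = b"G", b"A"
        cpg_obs = np.asarray(spec.cpg_positions, dtype=int) + 1

    is_conv_base = refarr == conv_from
    cpg_in = cpg_obs[cpg_obs < L]
    cpg_mask = np.zeros(L, dtype=bool)
    cpg_mask[cpg_in] = True

    pattern = np.full(spec.n_cpgs, -1, dtype=int)
    covered = cpg_obs < L
    obs = read[cpg_in]
    calls = np.where(obs == conv_from, 1, np.where(obs == conv_to, 0, -1))
    pattern[covered] = calls

    noncpg_conv = is_conv_base & ~cpg_mask
    n_conv_sites = int(noncpg_conv.sum())
    if n_conv_sites:
        converted = int((read[noncpg_conv] == conv_to).sum())
        conversion_rate = converted / n_conv_sites
    else:
        conversion_rate = 1.0  # vacuously complete

    comparable = ~is_conv_base & ~cpg_mask
    n_comp = int(comparable.sum())
    mismatches = int((read[comparable] != refarr[comparable]).sum())
    mismatch_frac = mismatches / n_comp if n_comp else 0.0

    passed = mismatch_frac <= spec.max_mismatch_frac and conversion_rate >= spec.min_conversion
    reason = ""
    if not passed:
        parts = []
        if mismatch_frac > spec.max_mismatch_frac:
            parts.append(f"mismatch_frac {mismatch_frac:.3f} > {spec.max_mismatch_frac}")
        if conversion_rate < spec.min_conversion:
            parts.append(f"conversion_rate {conversion_rate:.3f} < {spec.min_conversion}")
        reason = "; ".join(parts)
    return ReadCall(tuple(pattern), conversion_rate, mismatch_frac, passed, reason, strand)


def call_reads(
    read_seqs: Sequence[str], spec: AmpliconSpec, strand: str = "top"
) -> list[ReadCall]:
    """Call a batch of reads; equal-length top-strand batches take a
    vectorised path (the common case for simulated or full-length
    amplicon reads), anything else falls back to per-read calling."""
    lengths = {len(s) for s in read_seqs}
    if strand != "top" or not read_seqs or len(lengths) != 1:
        return [call_read(s, spec, strand=strand) for s in read_seqs]
    L = min(lengths.pop(), len(spec.reference_seq))
    mat = np.frombuffer("".join(s[:L] for s in read_seqs).encode(), dtype="S1")
    mat = mat.reshape(len(read_seqs), L)
    refarr = np.frombuffer(spec.reference_seq.encode(), dtype="S1")[:L]

    cpg = np.asarray(spec.cpg_positions, dtype=int)
    cpg_in = cpg[cpg < L]
    covered = cpg < L
    is_c = refarr == b"C"
    cpg_mask = np.zeros(L, dtype=bool)
    cpg_mask[cpg_in] = True

    obs = mat[:, cpg_in]
    calls = np.where(obs == b"C", 1, np.where(obs == b"T", 0, -1))
    patterns = np.full((len(read_seqs), spec.n_cpgs), -1, dtype=int)
    patterns[:, covered] = calls

    noncpg_c = is_c & ~cpg_mask
    n_conv = int(noncpg_c.sum())
    if n_conv:
        conv_rate = (mat[:, noncpg_c] == b"T").sum(axis=1) / n_conv
    else:
        conv_rate = np.ones(len(read_seqs))
    comparable = ~is_c & ~cpg_mask
    n_comp = int(comparable.sum())
    if n_comp:
        mm = (mat[:, comparable] != refarr[comparable]).sum(axis=1) / n_comp
    else:
        mm = np.zeros(len(read_seqs))
    passed = (mm <= spec.max_mismatch_frac) & (conv_rate >= spec.min_conversion)
    return [
        ReadCall(tuple(patterns[i]), float(conv_rate[i]), float(mm[i]), bool(passed[i]))
        for i in range(len(read_seqs))
    ]


@dataclass
class ReadPatternTable:
    """Counts of binary methylation patterns for one sample and amplicon.

    Keys are strings over {0,1,?} of length n_cpgs; values are positive
    read counts. This is the substrate both for per-CpG DNAm levels and
    for single-read age prediction.
    """

    sample_id: str
    amplicon: str
    n_cpgs: int
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pat, c in self.counts.items():
            if len(pat) != self.n_cpgs:
                raise ValueError(
                    f"pattern {pat!r} length {len(pat)} != n_cpgs {self.n_cpgs}"
                )
            if c <= 0:
                raise ValueError(f"pattern {pat!r} has non-positive count {c}")

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    def pattern_array(self) -> tuple[np.ndarray, np.ndarray]:
        """(P, n_cpgs) float array with NaN for '?', and count vector."""
        pats = sorted(self.counts)
        arr = np.full((len(pats), self.n_cpgs), np.nan)
        for r, p in enumerate(pats):
            for c, ch in enumerate(p):
                if ch != "?":
                    arr[r, c] = float(ch)
        return arr, np.array([self.counts[p] for p in pats], dtype=float)


def build_pattern_table(
    reads: Iterable[ReadCall], sample_id: str, spec: AmpliconSpec
) -> ReadPatternTable:
    """Tabulate QC-passing reads into pattern counts.

    Patterns with missing calls are kept with '?' placeholders; failing
    reads are dropped. Zero passing reads yields an empty table with a
    warning rather than an error.
    """
    counts: dict[str, int] = {}
    n_total = 0
    for rc in reads:
        n_total += 1
        if not rc.passed_qc:
            continue
        pat = rc.pattern_string()
        counts[pat] = counts.get(pat, 0) + 1
    if n_total and not counts:
        warnings.warn(
            f"{sample_id}/{spec.name}: no reads passed QC out of {n_total}",
            stacklevel=2,
        )
    return ReadPatternTable(sample_id, spec.name, spec.n_cpgs, counts)


def beta_from_patterns(table: ReadPatternTable) -> np.ndarray:
    """Per-CpG DNAm level (beta, fraction) from a pattern table.

    beta_i = methylated calls / non-missing calls at CpG i, weighted by
    pattern counts; CpGs with no non-missing calls come back NaN.
    """
    betas = np.full(table.n_cpgs, np.nan)
    if not table.counts:
        return betas
    arr, w = table.pattern_array()
    obs = ~np.isnan(arr)
    denom = (obs * w[:, None]).sum(axis=0)
    meth = (np.nan_to_num(arr) * w[:, None]).sum(axis=0)
    good = denom > 0
    betas[good] = meth[good] / denom[good]
    return betas


def neighbor_correlation(table: ReadPatternTable) -> np.ndarray:
    """CpG x CpG Pearson correlation of methylation state across reads.

    Each pair uses reads non-missing at both CpGs, expanded by pattern
    count. Pairs where either CpG has zero variance are NaN (flagged by
    a warning, not an error); the diagonal is 1 where defined.
    """
    C = table.n_cpgs
    out = np.full((C, C), np.nan)
    if not table.counts:
        return out
    arr, w = table.pattern_array()
    obs = ~np.isnan(arr)
    x = np.nan_to_num(arr)
    any_degenerate = False
    for i in range(C):
        for j in range(i, C):
            m = obs[:, i] & obs[:, j]
            wt = w[m]
            n = wt.sum()
            if n <= 1:
                continue
            xi, xj = x[m, i], x[m, j]
            mi = (wt * xi).sum() / n
            mj = (wt * xj).sum() / n
            vi = (wt * (xi - mi) ** 2).sum()
            vj = (wt * (xj - mj) ** 2).sum()
            if vi <= 0 or vj <= 0:
                if i != j:
                    any_degenerate = True
                continue
            cov = (wt * (xi - mi) * (xj - mj)).sum()
            r = cov / np.sqrt(vi * vj)
            out[i, j] = out[j, i] = float(np.clip(r, -1.0, 1.0))
            if i == j:
                out[i, i] = 1.0
    if any_degenerate:
        warnings.warn(
            f"{table.sample_id}/{table.amplicon}: zero-variance CpG pairs left undefined",
            stacklevel=2,
        )
    return out
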