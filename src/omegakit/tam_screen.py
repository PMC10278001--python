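"""Analyze an 8N TAM-library cleavage screen.

The target-adjacent motif (TAM) is the short sequence 5' of the target that
a TnpB nuclease requires for double-stranded DNA cleavage — the OMEGA-system
analogue of a PAM.  A screen sequences two libraries derived from a plasmid
pool with eight fully randomized bases at the TAM position: the *input*
library (everything) and the *cleaved* library (molecules the nuclease cut).
This module extracts the randomized window from both read sets, computes
per-position nucleotide enrichment of cleaved over input, summarizes each
position's information content, and calls an IUPAC consensus motif with an
active/inactive verdict.

Statistic: per-position information content is the Kullback-Leibler
divergence (in bits) of the cleaved-set base frequencies from the input-set
frequencies, with Laplace smoothing.  Normalizing against the sequenced
input library (rather than a uniform assumption) absorbs synthesis bias in
the 8N pool; a uniform background is available by passing ``input_table=None``.

Default thresholds were calibrated on the synthetic screen generator at its
default operating point (library of 50,000 molecules, cleavage probability
0.9 for matching / 0.001 for background molecules); see the package methods
documentation for the operating-characteristic analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .locus_model import (
    BASES_TO_IUPAC,
    DNA_BASES,
    Read,
    encode_sequence,
)

#: Positions are called when their cleaved-vs-input KL divergence reaches
#: this many bits (calibrated; see module docstring).
DEFAULT_IC_CALL_THRESHOLD = 0.15
#: A base enters the IUPAC consensus at a called position when its cleaved
#: frequency reaches this fraction.
DEFAULT_BASE_INCLUDE_FRAC = 0.25
#: Minimum cleaved-library window count for an ``active`` verdict
#: (calibrated; see module docstring).
DEFAULT_MIN_TOTAL_WINDOWS = 70


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class TamCountTable:
    """Per-position base counts over the randomized window of one library."""

    window_len: int
    counts: np.ndarray  # (window_len, 4) over A,C,G,T
    n_windows: int
    n_rejected: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (self.window_len, 4):
            raise ValueError("counts must have shape (window_len, 4)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not (self.counts.sum(axis=1) == self.n_windows).all():
            raise ValueError("each position's counts must sum to n_windows")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, columns=list(DNA_BASES)).rename_axis("position").reset_index()


@dataclass
class TamEnrichmentResult:
    """Per-position enrichment/information content and the motif call.

    ``enrichment[j, b]`` is ``log2((f_cleaved + pseudo) / (f_input + pseudo))``
    at window position ``j`` for base ``b``; ``ic_bits[j]`` is the KL
    divergence (bits) of cleaved from input frequencies at ``j``.  The motif
    call fields (``consensus``, ``called_span``, ``active``, ``at_fraction``)
    are populated by :func:`call_tam`.
    """

    enrichment: np.ndarray
    ic_bits: np.ndarray
    cleaved_freq: np.ndarray
    n_cleaved_windows: int
    consensus: str = ""
    called_span: tuple[int, int] | None = None
    active: bool = False
    at_fraction: float | None = None


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def extract_windows(
    reads: list[Read],
    upstream_anchor: str,
    downstream_anchor: str,
    window_len: int = 8,
    max_anchor_mismatch: int = 1,
) -> TamCountTable:
    """Locate the randomized window between the two backbone anchors.

    A read contributes one window iff both anchors are found (Hamming
    distance <= ``max_anchor_mismatch`` each) separated by exactly
    ``window_len`` bases; the leftmost qualifying placement is used.  Windows
    containing N are rejected.  Raises if no read yields a window.
    """
    if not upstream_anchor or not downstream_anchor:
        raise ValueError("anchors must be non-empty")
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    up = encode_sequence(upstream_anchor)
    down = encode_sequence(downstream_anchor)
    la, ld = len(up), len(down)
    span = la + window_len + ld

    if not reads:
        raise ValueError("no informative reads: empty read set")

    max_len = max(len(r.sequence) for r in reads)
    mat = np.full((len(reads), max_len), 254, dtype=np.uint8)  # pad != any code
    for i, r in enumerate(reads):
        mat[i, : len(r.sequence)] = encode_sequence(r.sequence)

    n_offsets = max_len - span + 1
    counts = np.zeros((window_len, 4), dtype=int)
    n_windows = 0
    n_rejected = 0
    if n_offsets > 0:
        found = np.full(len(reads), -1, dtype=int)
        for off in range(n_offsets):
            mm_up = (mat[:, off : off + la] != up).sum(axis=1)
            d0 = off + la + window_len
            mm_down = (mat[:, d0 : d0 + ld] != down).sum(axis=1)
            ok = (mm_up <= max_anchor_mismatch) & (mm_down <= max_anchor_mismatch)
            newly = ok & (found < 0)
            found[newly] = off
        hit = found >= 0
        w0 = found[hit] + la
        win = mat[np.flatnonzero(hit)[:, None], w0[:, None] + np.arange(window_len)]
        clean = (win < 4).all(axis=1)
        win = win[clean]
        n_windows = int(win.shape[0])
        n_rejected = len(reads) - n_windows
        for j in range(window_len):
            counts[j] = np.bincount(win[:, j], minlength=4)
    else:
        n_rejected = len(reads)

    if n_windows == 0:
        raise ValueError("no informative reads: no window passed anchor matching")
    return TamCountTable(window_len=window_len, counts=counts,
                         n_windows=n_windows, n_rejected=n_rejected)


def compute_enrichment(
    cleaved: TamCountTable,
    input_table: TamCountTable | None,
    pseudocount: float = 1.0,
) -> TamEnrichmentResult:
    """Per-position log2 enrichment and KL information content (bits).

    Frequencies are computed with ``pseudocount`` added to every count cell
    (Laplace smoothing).  ``input_table=None`` uses a uniform background.
    Information content is floored at 0 to absorb floating-point noise.
    """
    if cleaved.n_windows < 1:
        raise ValueError("cleaved table has no windows")
    w = cleaved.window_len
    if input_table is not None:
        if input_table.window_len != w:
            raise ValueError(
                f"window length mismatch: cleaved {w} vs input {input_table.window_len}"
            )
        if input_table.n_windows < 1:
            raise ValueError("input table has no windows")
        ci = input_table.counts + pseudocount
        fi = ci / ci.sum(axis=1, keepdims=True)
    else:
        fi = np.full((w, 4), 0.25)
    cc = cleaved.counts + pseudocount
    fc = cc / cc.sum(axis=1, keepdims=True)
    enrichment = np.log2(fc / fi)
    ic_bits = np.maximum((fc * np.log2(fc / fi)).sum(axis=1), 0.0)
    return TamEnrichmentResult(
        enrichment=enrichment,
        ic_bits=ic_bits,
        cleaved_freq=fc,
        n_cleaved_windows=cleaved.n_windows,
    )


def call_tam(
    result: TamEnrichmentResult,
    ic_call_threshold: float = DEFAULT_IC_CALL_THRESHOLD,
    base_include_frac: float = DEFAULT_BASE_INCLUDE_FRAC,
    min_total_windows: int = DEFAULT_MIN_TOTAL_WINDOWS,
) -> TamEnrichmentResult:
    """Call the IUPAC consensus TAM from an enrichment result.

    Positions whose information content reaches ``ic_call_threshold`` are
    called; ``called_span`` is the minimal contiguous interval covering them,
    and every position in the span contributes the bases whose cleaved
    frequency reaches ``base_include_frac`` to the consensus.  ``active``
    additionally requires at least ``min_total_windows`` cleaved windows; an
    inactive result carries an empty consensus.  ``at_fraction`` is the
    cleaved-frequency-weighted A/T share of the consensus bases.
    """
    called = np.flatnonzero(result.ic_bits >= ic_call_threshold)
    if called.size == 0:
        return replace(result, consensus="", called_span=None, active=False,
                       at_fraction=None)

    span = (int(called[0]), int(called[-1]) + 1)
    active = result.n_cleaved_windows >= min_total_windows
    if not active:
        return replace(result, consensus="", called_span=None, active=False,
                       at_fraction=None)

    consensus_chars: list[str] = []
    at_weight = 0.0
    total_weight = 0.0
    for j in range(*span):
        freqs = result.cleaved_freq[j]
        included = frozenset(
            DNA_BASES[b] for b in range(4) if freqs[b] >= base_include_frac
        )
        if not included:  # cannot happen for base_include_frac <= 0.25
            included = frozenset(DNA_BASES[int(freqs.argmax())])
        consensus_chars.append(BASES_TO_IUPAC[included])
        for base in included:
            weight = float(freqs[DNA_BASES.index(base)])
            total_weight += weight
            if base in "AT":
                at_weight += weight
    return replace(
        result,
        consensus="".join(consensus_chars),
        called_span=span,
        active=True,
        at_fraction=at_weight / total_weight if total_weight else None,
    )


def logo_matrix(result: TamEnrichmentResult) -> pd.DataFrame:
    """Long-format (position, base, height) table for logo plotting.

    Height is the conventional ``frequency x position information``, so each
    stack's total height is the position's information content in bits.
    """
    rows = []
    for j in range(result.cleaved_freq.shape[0]):
        for b, base in enumerate(DNA_BASES):
            rows.append(
                {"position": j, "base": base,
                 "height": float(result.cleaved_freq[j, b] * result.ic_bits[j])}
            )
    return pd.DataFrame(rows)
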