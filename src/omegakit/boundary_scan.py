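"""Guide-scaffold boundary detection and mRNA complementarity scanning.

The omegaRNA scaffold lies within the transposon and is conserved among
related loci, while the guide is locus-specific genomic sequence 3' of the
transposon right end (RE).  In an alignment of the 3' ends of related loci,
the RE boundary therefore appears as a sharp drop in per-column conservation;
``find_boundary`` locates the *downstream-most* column at which a windowed
conservation drop qualifies.

``complementarity_scan`` supports the cis-inhibition hypothesis that a region
of the nuclease mRNA can base-pair with (and so disrupt) the processed
omegaRNA scaffold: it scores every fixed-length mRNA window by the longest
contiguous, gap-free stretch of Watson-Crick pairing it can form with any
scaffold segment, i.e. the longest common substring between the window and
the reverse complement of the scaffold.  This is a sequence-level surrogate,
deliberately simpler than thermodynamic co-folding; it ranks candidate
inhibitory windows and makes no mechanistic claim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .locus_model import DNA_BASES, encode_sequence, reverse_complement

GAP_CHARS = frozenset("-.")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ColumnConservation:
    """Per-column conservation of an alignment.

    ``scores[c]`` is the frequency of the modal A/C/G/T base among non-gap
    characters in column ``c`` (0 for all-gap columns); ``gap_frac[c]`` is
    the fraction of gap characters.
    """

    n_columns: int
    scores: np.ndarray
    gap_frac: np.ndarray


@dataclass
class BoundaryCall:
    """A called conservation-drop boundary, or a null call (column=None)."""

    column: int | None
    drop_size: float
    upstream_mean: float
    downstream_mean: float


@dataclass
class ComplementarityHit:
    """One mRNA window scored for pairing potential against the scaffold."""

    mrna_window: tuple[int, int]
    score: int
    rank: int


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _rows_of(msa: list) -> list[tuple[str, str]]:
    """Accept either aligned strings or (id, aligned string) pairs."""
    if msa and isinstance(msa[0], str):
        return [(f"seq_{i}", s) for i, s in enumerate(msa)]
    return list(msa)


def column_conservation(msa: list) -> ColumnConservation:
    """Modal-base frequency per alignment column.

    Requires >= 3 sequences of equal aligned length.  Characters other than
    A/C/G/T or gaps (e.g. N) count in the non-gap denominator but never as
    the modal base.
    """
    rows = _rows_of(msa)
    if len(rows) < 3:
        raise ValueError("alignment must contain at least 3 sequences")
    lengths = {len(seq) for _rid, seq in rows}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: sequences have unequal aligned lengths")
    n_cols = lengths.pop()
    n_seqs = len(rows)

    mat = np.empty((n_seqs, n_cols), dtype="U1")
    for i, (_rid, seq) in enumerate(rows):
        mat[i] = list(seq.upper())

    is_gap = np.isin(mat, list(GAP_CHARS))
    gap_count = is_gap.sum(axis=0)
    non_gap = n_seqs - gap_count
    base_counts = np.stack([(mat == b).sum(axis=0) for b in DNA_BASES])  # (4, n_cols)
    modal = base_counts.max(axis=0)

    scores = np.zeros(n_cols, dtype=float)
    has = non_gap > 0
    scores[has] = modal[has] / non_gap[has]
    return ColumnConservation(
        n_columns=n_cols, scores=scores, gap_frac=gap_count / n_seqs
    )


def find_boundary(
    conservation: ColumnConservation,
    window: int = 5,
    drop_threshold: float = 0.4,
    min_upstream: float = 0.7,
    max_gap_frac: float = 0.5,
) -> BoundaryCall:
    """Locate the downstream-most sharp conservation drop.

    For each candidate column ``c`` the mean conservation over
    ``[c-window, c)`` is compared with ``[c, c+window)``; ``c`` qualifies
    when the upstream mean reaches ``min_upstream``, the drop reaches
    ``drop_threshold``, and the column is not gap-dominated
    (``gap_frac[c] <= max_gap_frac``).  Among qualifying candidates the one
    with the largest ``c`` is returned; a null call (column None) is a valid
    outcome.
    """
    scores = conservation.scores
    n = conservation.n_columns
    if n < 2 * window:
        raise ValueError("alignment too short for the requested window")
    best: BoundaryCall | None = None
    for c in range(window, n - window + 1):
        if c < n and conservation.gap_frac[c] > max_gap_frac:
            continue
        up = float(scores[c - window : c].mean())
        down = float(scores[c : c + window].mean())
        drop = up - down
        if up >= min_upstream and drop >= drop_threshold:
            best = BoundaryCall(column=c, drop_size=drop,
                                upstream_mean=up, downstream_mean=down)
    if best is None:
        return BoundaryCall(column=None, drop_size=0.0,
                            upstream_mean=float("nan"), downstream_mean=float("nan"))
    return best


def project_boundary(msa: list, column: int) -> dict[str, int]:
    """Project an alignment column onto each sequence's ungapped coordinates
    (number of non-gap characters strictly before the column)."""
    rows = _rows_of(msa)
    out: dict[str, int] = {}
    for rid, seq in rows:
        out[rid] = sum(1 for ch in seq[:column] if ch not in GAP_CHARS)
    return out


def complementarity_scan(
    mrna: str,
    scaffold: str,
    window: int = 50,
    wobble: bool = False,
) -> list[ComplementarityHit]:
    """Score every mRNA window by its best contiguous pairing to the scaffold.

    A window's score is the maximal number of contiguous, gap-free
    Watson-Crick base pairings it can form with an equal-length scaffold
    segment — equivalently, the longest common substring between the window
    and the reverse complement of the scaffold.  With ``wobble=True``, G·U
    (here G·T) pairs also count.  All windows are returned, ranked by score
    descending with ties broken by smaller coordinate; ``rank`` is 1-based.
    """
    if not scaffold:
        raise ValueError("scaffold must be non-empty")
    if window > len(mrna):
        raise ValueError("window longer than the mRNA")
    rc = reverse_complement(scaffold)
    m = encode_sequence(mrna)
    r = encode_sequence(rc)

    match = m[:, None] == r[None, :]
    if wobble:
        # G (mrna) pairs scaffold T -> rc base A; T (mrna) pairs scaffold G -> rc base C
        g, a = DNA_BASES.index("G"), DNA_BASES.index("A")
        t, c = DNA_BASES.index("T"), DNA_BASES.index("C")
        match |= (m[:, None] == g) & (r[None, :] == a)
        match |= (m[:, None] == t) & (r[None, :] == c)
    # exclude any non-ACGT characters from pairing
    match &= (m[:, None] < 4) & (r[None, :] < 4)

    # run[i, j]: length of the contiguous match run ending at (i, j)
    n, k = match.shape
    run = np.zeros((n, k), dtype=np.int32)
    run[0] = match[0]
    for i in range(1, n):
        run[i, 0] = match[i, 0]
        run[i, 1:] = np.where(match[i, 1:], run[i - 1, :-1] + 1, 0)
    best_run = run.max(axis=1)  # best run ending at each mRNA position

    hits: list[ComplementarityHit] = []
    starts = np.arange(n - window + 1)
    for s in starts:
        idx = np.arange(s, s + window)
        score = int(np.minimum(best_run[idx], idx - s + 1).max())
        hits.append(ComplementarityHit(mrna_window=(int(s), int(s + window)),
                                       score=score, rank=0))
    hits.sort(key=lambda h: (-h.score, h.mrna_window[0]))
    return [ComplementarityHit(h.mrna_window, h.score, i + 1) for i, h in enumerate(hits)]


def truncation_panel(mrna: str, endpoints: list[int]) -> list[tuple[str, str]]:
    """3' truncation panel: labelled prefixes ``mrna[0:e)`` per endpoint."""
    out: list[tuple[str, str]] = []
    for e in endpoints:
        if not (0 < e <= len(mrna)):
            raise ValueError(f"truncation endpoint {e} outside (0, {len(mrna)}]")
        out.append((f"trunc_{e}", mrna[:e]))
    return out
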