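"""Call omegaRNA 5' processing sites from RACE reads.

Pipeline: trim the ligated 5' adaptor, map each read's 5' end onto the locus
template with a seed-anchored search, accumulate a per-position start
profile, classify the locus (``clear`` / ``multiple`` / ``none``), and emit
the scaffold annotation whose 3' end is the locus's RE boundary.

Because the assay primes reverse transcription from the 3' end of the
omegaRNA scaffold, the caller only ever reads 5' structure: sequence added
3' of the guide cannot change any start call.

Classification quantifies "a substantial portion of reads at a single start
site" as a dominant peak holding >= ``dominant_frac`` of mapped 5' ends.
Mapped ends are aggregated into peaks by clustering counts within
``cluster_radius`` positions of each local maximum before ranking, because
ligation and RT chemistry blur true processing sites by a base or two; the
reported site is the modal position of its peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .locus_model import IntervalAnnotation, LocusRecord, Read, encode_sequence

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ReadStartProfile:
    """Per-template-position counts of mapped read 5' ends."""

    template_id: str
    counts: np.ndarray
    n_mapped: int
    n_unmapped: int
    n_untrimmed: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("start counts must be non-negative")
        if int(self.counts.sum()) != self.n_mapped:
            raise ValueError("sum(counts) must equal n_mapped")

    @property
    def n_total(self) -> int:
        return self.n_mapped + self.n_unmapped + self.n_untrimmed


@dataclass
class StartSiteCall:
    """Called processing site(s) and the three-way locus classification.

    ``sites`` holds ``(position, fraction_of_mapped_starts)`` pairs sorted by
    fraction descending; fractions are over disjoint peaks so they sum to at
    most 1.  ``fallback_longest_start`` is the 5'-most observed start (the
    longest RNA species), used downstream when no site can be called.
    """

    classification: str  # "clear" | "multiple" | "none"
    sites: list[tuple[int, float]]
    fallback_longest_start: int | None


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def trim_adapter(
    reads: list[Read], adapter: str, max_mismatch: int = 1
) -> tuple[list[Read], int]:
    """Remove the 5' adaptor from each read prefix (Hamming tolerance).

    Reads whose prefix does not match within ``max_mismatch`` substitutions,
    and reads that would be empty after trimming, are excluded and counted.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    alen = len(adapter)
    trimmed: list[Read] = []
    n_untrimmed = 0
    for read in reads:
        if len(read.sequence) <= alen:
            n_untrimmed += 1
            continue
        mism = sum(a != b for a, b in zip(adapter, read.sequence))
        if mism > max_mismatch:
            n_untrimmed += 1
            continue
        quals = read.qualities[alen:] if read.qualities is not None else None
        trimmed.append(Read(id=read.id, sequence=read.sequence[alen:], qualities=quals))
    return trimmed, n_untrimmed


def map_read_starts(
    reads: list[Read],
    template: str,
    template_id: str = "template",
    min_anchor: int = 20,
    max_mismatch_rate: float = 0.1,
) -> ReadStartProfile:
    """Map read 5' ends to the template by anchoring the first
    ``min_anchor`` bases (ungapped, substitution-tolerant).

    A read maps if its anchor matches the template somewhere with at most
    ``floor(max_mismatch_rate * min_anchor)`` mismatches; among best-scoring
    positions the leftmost wins.  Reads shorter than the anchor are unmapped.
    """
    if len(template) < min_anchor:
        raise ValueError("template shorter than min_anchor")
    length = len(template)
    counts = np.zeros(length, dtype=int)
    max_mm = int(np.floor(max_mismatch_rate * min_anchor))

    anchors = []
    keep_idx = []
    for i, read in enumerate(reads):
        if len(read.sequence) >= min_anchor:
            anchors.append(encode_sequence(read.sequence[:min_anchor]))
            keep_idx.append(i)
    n_unmapped = len(reads) - len(anchors)
    n_mapped = 0
    if anchors:
        template_windows = np.lib.stride_tricks.sliding_window_view(
            encode_sequence(template), min_anchor
        )  # (n_positions, min_anchor)
        anchor_mat = np.stack(anchors)
        # chunk over reads to bound the (reads x positions x anchor) bool array
        chunk = max(1, int(4e7) // (template_windows.shape[0] * min_anchor))
        for lo in range(0, anchor_mat.shape[0], chunk):
            sub = anchor_mat[lo : lo + chunk]
            mism = (sub[:, None, :] != template_windows[None, :, :]).sum(axis=2)
            best_pos = mism.argmin(axis=1)  # leftmost minimum
            best_mm = mism[np.arange(sub.shape[0]), best_pos]
            ok = best_mm <= max_mm
            np.add.at(counts, best_pos[ok], 1)
            n_mapped += int(ok.sum())
            n_unmapped += int((~ok).sum())

    return ReadStartProfile(
        template_id=template_id,
        counts=counts,
        n_mapped=n_mapped,
        n_unmapped=n_unmapped,
        n_untrimmed=0,
    )


def call_start_sites(
    profile: ReadStartProfile,
    dominant_frac: float = 0.5,
    secondary_frac: float = 0.2,
    min_mapped: int = 50,
    cluster_radius: int = 2,
) -> StartSiteCall:
    """Classify a start profile as ``clear``, ``multiple`` or ``none``.

    Counts are greedily clustered: the highest remaining position becomes a
    peak, absorbs all counts within ``cluster_radius``, and the peak's
    fraction of mapped starts is scored.  ``clear`` requires the top peak to
    hold >= ``dominant_frac``; ``multiple`` requires >= 2 peaks each holding
    >= ``secondary_frac`` with none dominant; anything else (including fewer
    than ``min_mapped`` mapped reads) is ``none``.  Ties in peak height go to
    the smaller (5'-most) coordinate.
    """
    counts = profile.counts.astype(int)
    nonzero = np.flatnonzero(counts)
    fallback = int(nonzero[0]) if nonzero.size else None

    if profile.n_mapped < min_mapped or nonzero.size == 0:
        return StartSiteCall(classification="none", sites=[], fallback_longest_start=fallback)

    work = counts.copy()
    peaks: list[tuple[int, float]] = []
    while work.max() > 0:
        pos = int(work.argmax())  # argmax returns the smallest index on ties
        lo = max(0, pos - cluster_radius)
        hi = min(len(work), pos + cluster_radius + 1)
        mass = int(work[lo:hi].sum())
        work[lo:hi] = 0
        frac = mass / profile.n_mapped
        if frac >= secondary_frac:
            peaks.append((pos, frac))
    peaks.sort(key=lambda s: (-s[1], s[0]))

    n_dominant = sum(1 for _p, f in peaks if f >= dominant_frac)
    if n_dominant == 1:
        classification = "clear"
        sites = peaks
    elif len(peaks) >= 2:
        classification = "multiple"
        sites = peaks
    else:
        classification = "none"
        sites = []
    return StartSiteCall(classification=classification, sites=sites,
                         fallback_longest_start=fallback)


def annotate_scaffold(
    call: StartSiteCall, locus: LocusRecord, guide_len: int = 20
) -> IntervalAnnotation:
    """Annotate the processed omegaRNA scaffold on the locus.

    The scaffold runs from the called 5' processing site to the locus's RE
    boundary (the guide start).  When no site was called the 5'-most
    observed start — the longest RNA species — is used instead.  ``guide_len``
    is only used to log the processed-species length (scaffold + guide).
    """
    if call.classification != "none" and call.sites:
        start = call.sites[0][0]
        score: float | None = call.sites[0][1]
    else:
        if call.fallback_longest_start is None:
            raise ValueError("no observed starts: cannot annotate scaffold")
        start = call.fallback_longest_start
        score = None
    end = locus.re_boundary
    if start >= end:
        raise ValueError(
            f"start beyond RE boundary: called start {start} is not upstream "
            f"of the scaffold 3' end {end}"
        )
    from .locus_model import logger

    logger.info(
        "annotate_scaffold: locus %s scaffold %d nt, processed species %d nt "
        "(positions are 1-based in this message: start %d)",
        locus.id, end - start, end - start + guide_len, start + 1,
    )
    return IntervalAnnotation(ref_id=locus.id, start=start, end=end,
                              label="scaffold", score=score)
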