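"""Seeded generators emulating the three assays the toolkit analyzes.

Each generator reproduces the statistical structure its downstream caller
assumes, and returns a :class:`SyntheticTruth` sidecar carrying every
parameter plus the derived ground truth, so recovery can be tested without
any deposited sequencing data.

* ``simulate_race_reads`` — a 5' RACE library: read 5' ends cluster at one
  or more true processing sites with discretized-Gaussian positional jitter,
  a uniform background of degradation/incomplete-extension starts, a fixed
  5' adaptor on every read, and independent per-base substitution errors.
* ``simulate_tam_screen`` — an 8N TAM-library cleavage screen: every library
  molecule carries two constant backbone anchors around eight uniformly
  random bases; a molecule is cleaved (enters the cleaved library) with high
  probability when its window matches the ground-truth TAM (IUPAC-aware) and
  with a small background probability otherwise.
* ``simulate_msa`` — an ortholog alignment: near-identical scaffold columns
  (low substitution rate) followed by independent uniform-random guide
  columns, so the scaffold/guide boundary is a planted conservation drop.
* ``simulate_cleavage_fragments`` — bookkeeping for a single double-strand
  cut: fragment lengths of a linear substrate cleaved at one position.

All randomness in a call flows from one ``numpy`` generator seeded by the
``seed`` field, so identical parameters give byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .locus_model import (
    DNA_BASES,
    IUPAC_TO_BASES,
    Read,
    decode_sequence,
    encode_sequence,
    write_json,
)

#: Fixed synthetic 5' adaptor ligated to every simulated RACE read
#: (DNA form of a small-RNA 5' SR adaptor).
DEFAULT_RACE_ADAPTER = "GTTCAGAGTTCTACAGTCCGACGATC"

#: Default constant backbone anchors flanking the 8N window in simulated
#: TAM-library reads.  The real read structure after the two-primer
#: amplification is configurable precisely because it is library-specific.
DEFAULT_UPSTREAM_ANCHOR = "ACGGCTAGCTCAGT"
DEFAULT_DOWNSTREAM_ANCHOR = "TGGAATTCTCGGGT"

#: Default per-base substitution error rate (substitution-dominated
#: short-read error model; indels are not modelled).
DEFAULT_SUBST_ERROR = 0.001


@dataclass
class SyntheticTruth:
    """Ground-truth sidecar emitted beside every generated dataset.

    ``params`` carries every generator parameter (sufficient to regenerate
    the dataset bit-identically given the seed); ``truth`` carries the
    derived quantities recovery tests compare against.
    """

    generator: str
    params: dict
    truth: dict

    def to_json(self, path: str | Path) -> None:
        write_json({"generator": self.generator, "params": self.params,
                    "truth": self.truth}, path)


def _apply_substitutions(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base (codes 0..3) independently with probability
    ``rate``, always to a different base."""
    if rate <= 0:
        return codes
    mask = rng.random(codes.shape) < rate
    n = int(mask.sum())
    if n:
        codes = codes.copy()
        codes[mask] = (codes[mask] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
    return codes


# ---------------------------------------------------------------------------
# 5' RACE
# ---------------------------------------------------------------------------

@dataclass
class RaceSimParams:
    """Parameters of a simulated 5' RACE library.

    true_sites
        ``(position, weight)`` pairs; weights must sum to 1.  Positions are
        0-based template coordinates of true processing sites.
    jitter_sd
        Standard deviation (in positions) of the discretized Gaussian noise
        on each non-background read's 5' end.
    background_rate
        Fraction of reads whose 5' end is uniform over the template
        (degradation / premature reverse-transcription stops).
    """

    template: str
    true_sites: Sequence[tuple[int, float]]
    n_reads: int
    jitter_sd: float = 1.0
    background_rate: float = 0.05
    subst_error: float = DEFAULT_SUBST_ERROR
    read_length: int = 300
    seed: int = 0
    adapter: str = DEFAULT_RACE_ADAPTER

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if not (0 <= self.background_rate <= 1 and 0 <= self.subst_error <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if not self.true_sites:
            raise ValueError("at least one true site is required")
        for pos, _w in self.true_sites:
            if not (0 <= pos < len(self.template)):
                raise ValueError(f"site position {pos} outside template")
        total = sum(w for _p, w in self.true_sites)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"site weights must sum to 1 (got {total})")


def simulate_race_reads(params: RaceSimParams) -> tuple[list[Read], SyntheticTruth]:
    """Generate a RACE read set and its ground truth.

    Each non-background read starts at ``round(site + N(0, jitter_sd))``
    clipped into the template, extends 3'-ward up to ``read_length`` or the
    template end (truncation, never an error), receives the fixed 5' adaptor,
    and then accumulates independent substitution errors over its full
    length (adaptor included).
    """
    rng = np.random.default_rng(params.seed)
    template_codes = encode_sequence(params.template)
    length = len(params.template)
    n = params.n_reads

    positions = np.array([p for p, _w in params.true_sites])
    weights = np.array([w for _p, w in params.true_sites], dtype=float)
    weights = weights / weights.sum()

    is_background = rng.random(n) < params.background_rate
    site_choice = rng.choice(len(positions), size=n, p=weights)
    jitter = rng.normal(0.0, params.jitter_sd, size=n) if params.jitter_sd > 0 else np.zeros(n)
    starts = np.rint(positions[site_choice] + jitter).astype(int)
    starts = np.clip(starts, 0, length - 1)
    n_bg = int(is_background.sum())
    if n_bg:
        starts[is_background] = rng.integers(0, length, size=n_bg)

    adapter_codes = encode_sequence(params.adapter)
    read_lengths = np.minimum(params.read_length, length - starts)
    reads: list[Read] = []
    for i in range(n):
        s = int(starts[i])
        body = template_codes[s : s + int(read_lengths[i])]
        codes = _apply_substitutions(
            np.concatenate([adapter_codes, body]), params.subst_error, rng
        )
        reads.append(Read(id=f"race_{i:06d}", sequence=decode_sequence(codes)))

    hist = np.bincount(starts, minlength=length)
    truth = SyntheticTruth(
        generator="simulate_race_reads",
        params={**asdict(params), "true_sites": [list(s) for s in params.true_sites]},
        truth={
            "true_sites": [list(s) for s in params.true_sites],
            "start_histogram": hist.tolist(),
            "n_background": n_bg,
        },
    )
    return reads, truth


# ---------------------------------------------------------------------------
# 8N TAM screen
# ---------------------------------------------------------------------------

@dataclass
class TamSimParams:
    """Parameters of a simulated 8N TAM-library cleavage screen.

    true_tam
        Ground-truth motif as an IUPAC string of length 1..8 anchored at
        ``tam_offset`` within the 8N window, or ``None`` for an inactive
        nuclease (pure background cleavage).
    cleave_rate_match / cleave_rate_background
        Probability that a matching / non-matching molecule enters the
        cleaved library.
    """

    true_tam: str | None
    n_library: int
    cleave_rate_match: float = 0.9
    cleave_rate_background: float = 0.001
    tam_offset: int = 0
    window_len: int = 8
    upstream_anchor: str = DEFAULT_UPSTREAM_ANCHOR
    downstream_anchor: str = DEFAULT_DOWNSTREAM_ANCHOR
    subst_error: float = DEFAULT_SUBST_ERROR
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_library < 1:
            raise ValueError("n_library must be >= 1")
        if self.true_tam is not None:
            if not (1 <= len(self.true_tam) <= self.window_len):
                raise ValueError("true_tam length must be in 1..window_len")
            if self.tam_offset + len(self.true_tam) > self.window_len:
                raise ValueError("true_tam does not fit in the window at tam_offset")
            bad = set(self.true_tam) - set(IUPAC_TO_BASES)
            if bad:
                raise ValueError(f"true_tam contains non-IUPAC characters: {sorted(bad)}")
        if not (0 <= self.cleave_rate_background <= self.cleave_rate_match <= 1):
            raise ValueError("need 0 <= cleave_rate_background <= cleave_rate_match <= 1")
        if not (0 <= self.subst_error <= 1):
            raise ValueError("subst_error must lie in [0, 1]")
        if not self.upstream_anchor or not self.downstream_anchor:
            raise ValueError("anchors must be non-empty")


def _iupac_match_mask(windows: np.ndarray, motif: str, offset: int) -> np.ndarray:
    """Boolean mask of rows whose window matches ``motif`` at ``offset``."""
    mask = np.ones(windows.shape[0], dtype=bool)
    for k, ch in enumerate(motif):
        allowed = np.array([DNA_BASES.index(b) for b in sorted(IUPAC_TO_BASES[ch])],
                           dtype=np.uint8)
        mask &= np.isin(windows[:, offset + k], allowed)
    return mask


def _window_base_counts(windows: np.ndarray, window_len: int) -> list[list[int]]:
    return [np.bincount(windows[:, j], minlength=4).tolist() for j in range(window_len)]


def simulate_tam_screen(params: TamSimParams) -> tuple[list[Read], list[Read], SyntheticTruth]:
    """Generate (input_reads, cleaved_reads, truth) for a TAM screen.

    All molecules enter the input library; a molecule enters the cleaved
    library with ``cleave_rate_match`` if its 8N window matches the ground
    truth motif, else ``cleave_rate_background``.  Substitution errors are
    applied independently per library, after selection, so molecule identity
    (the shared read id) is preserved across libraries.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_library
    w = params.window_len
    windows = rng.integers(0, 4, size=(n, w), dtype=np.uint8)

    if params.true_tam is None:
        match = np.zeros(n, dtype=bool)
    else:
        match = _iupac_match_mask(windows, params.true_tam, params.tam_offset)
    p_cleave = np.where(match, params.cleave_rate_match, params.cleave_rate_background)
    cleaved_sel = rng.random(n) < p_cleave

    up = encode_sequence(params.upstream_anchor)
    down = encode_sequence(params.downstream_anchor)
    mol = np.concatenate(
        [np.broadcast_to(up, (n, len(up))), windows,
         np.broadcast_to(down, (n, len(down)))], axis=1,
    ).astype(np.uint8)

    input_codes = _apply_substitutions(mol, params.subst_error, rng)
    cleaved_idx = np.flatnonzero(cleaved_sel)
    cleaved_codes = _apply_substitutions(mol[cleaved_idx], params.subst_error, rng)

    input_reads = [
        Read(id=f"mol_{i:07d}", sequence=decode_sequence(input_codes[i]))
        for i in range(n)
    ]
    cleaved_reads = [
        Read(id=f"mol_{i:07d}", sequence=decode_sequence(cleaved_codes[k]))
        for k, i in enumerate(cleaved_idx)
    ]

    truth = SyntheticTruth(
        generator="simulate_tam_screen",
        params=asdict(params),
        truth={
            "true_tam": params.true_tam,
            "tam_offset": params.tam_offset,
            "n_matching_molecules": int(match.sum()),
            "n_cleaved": int(cleaved_sel.sum()),
            "input_window_counts": _window_base_counts(windows, w),
            "cleaved_window_counts": _window_base_counts(windows[cleaved_idx], w),
        },
    )
    return input_reads, cleaved_reads, truth


# ---------------------------------------------------------------------------
# Cleavage fragment bookkeeping
# ---------------------------------------------------------------------------

def simulate_cleavage_fragments(substrate_len: int, cut_pos: int) -> tuple[int, int]:
    """Fragment lengths of a linear substrate cut once at ``cut_pos``.

    A cut at either end produces no second fragment and is an error.
    """
    if not (0 < cut_pos < substrate_len):
        raise ValueError("no cleavage product: cut position at or beyond substrate end")
    return cut_pos, substrate_len - cut_pos


# ---------------------------------------------------------------------------
# Ortholog MSA
# ---------------------------------------------------------------------------

@dataclass
class MsaSimParams:
    """Parameters of a simulated ortholog alignment around the RE boundary.

    Scaffold columns are the given sequence with independent substitutions at
    ``scaffold_subst_rate``; guide columns are independent uniform-random
    bases per sequence (each locus targets a different genomic site).  The
    true boundary column equals the scaffold length.
    """

    n_seqs: int
    scaffold: str
    guide_len: int
    scaffold_subst_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seqs < 3:
            raise ValueError("n_seqs must be >= 3")
        if self.guide_len < 5:
            raise ValueError("guide_len must be >= 5")
        if not (0 <= self.scaffold_subst_rate <= 1):
            raise ValueError("scaffold_subst_rate must lie in [0, 1]")
        if set(self.scaffold) - set(DNA_BASES):
            raise ValueError("scaffold must be A/C/G/T only")


def simulate_msa(params: MsaSimParams) -> tuple[list[tuple[str, str]], SyntheticTruth]:
    """Generate an aligned (gap-free) ortholog set and its boundary truth."""
    rng = np.random.default_rng(params.seed)
    scaffold_codes = encode_sequence(params.scaffold)
    rows: list[tuple[str, str]] = []
    for i in range(params.n_seqs):
        scaf = _apply_substitutions(scaffold_codes.copy(), params.scaffold_subst_rate, rng)
        guide = rng.integers(0, 4, size=params.guide_len, dtype=np.uint8)
        rows.append((f"ortholog_{i:03d}", decode_sequence(np.concatenate([scaf, guide]))))
    truth = SyntheticTruth(
        generator="simulate_msa",
        params=asdict(params),
        truth={"boundary_column": len(params.scaffold)},
    )
    return rows, truth
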