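"""Adaptor trimming, 5' end mapping, start-site calling, scaffold annotation."""

import numpy as np
import pytest

from omegakit import (
    DEFAULT_RACE_ADAPTER,
    LocusRecord,
    RaceSimParams,
    Read,
    ReadStartProfile,
    annotate_scaffold,
    call_start_sites,
    map_read_starts,
    simulate_race_reads,
    trim_adapter,
)
from omegakit.race_startsite import StartSiteCall
from conftest import random_dna


def _profile(counts, n_extra_unmapped=0):
    counts = np.asarray(counts, dtype=int)
    return ReadStartProfile(
        template_id="t", counts=counts, n_mapped=int(counts.sum()),
        n_unmapped=n_extra_unmapped, n_untrimmed=0,
    )


# ---------------------------------------------------------------------------
# trim_adapter
# ---------------------------------------------------------------------------

def test_trim_exact_adapter_prefix():
    reads = [Read(id="r", sequence="GTTCAGACGT")]
    trimmed, n_untrimmed = trim_adapter(reads, "GTTCAG", max_mismatch=0)
    assert n_untrimmed == 0
    assert trimmed[0].sequence == "ACGT"


def test_read_without_adapter_is_counted_untrimmed():
    reads = [Read(id="r", sequence="AAAAAAAAAA")]
    trimmed, n_untrimmed = trim_adapter(reads, "GTTCAG", max_mismatch=1)
    assert trimmed == [] and n_untrimmed == 1


def test_read_empty_after_trimming_is_excluded():
    reads = [Read(id="r", sequence="GTTCAG")]
    trimmed, n_untrimmed = trim_adapter(reads, "GTTCAG", max_mismatch=0)
    assert trimmed == [] and n_untrimmed == 1


def brute_force_trim(seq: str, adapter: str, max_mismatch: int) -> str | None:
    """Independent oracle: Hamming prefix scan."""
    if len(seq) <= len(adapter):
        return None
    mism = sum(1 for a, b in zip(adapter, seq[: len(adapter)]) if a != b)
    if mism <= max_mismatch:
        return seq[len(adapter):]
    return None


def test_trim_adapter_agrees_with_brute_force_on_random_cases():
    rng = np.random.default_rng(20)
    for i in range(1000):
        adapter = random_dna(int(rng.integers(4, 12)), seed=2000 + i)
        seq = random_dna(int(rng.integers(1, 40)), seed=3000 + i)
        if rng.random() < 0.5:  # half the cases carry a mutated adapter prefix
            prefix = list(adapter)
            for k in range(len(prefix)):
                if rng.random() < 0.1:
                    prefix[k] = "ACGT"[int(rng.integers(0, 4))]
            seq = "".join(prefix) + seq
        max_mm = int(rng.integers(0, 3))
        expected = brute_force_trim(seq, adapter, max_mm)
        trimmed, n_untrimmed = trim_adapter([Read(id="r", sequence=seq)], adapter, max_mm)
        if expected is None:
            assert trimmed == [] and n_untrimmed == 1
        else:
            assert n_untrimmed == 0 and trimmed[0].sequence == expected


def test_trim_one_mismatch_within_tolerance():
    reads = [Read(id="r", sequence="GATCAGACGT")]
    trimmed, _ = trim_adapter(reads, "GTTCAG", max_mismatch=1)
    assert trimmed[0].sequence == "ACGT"


# ---------------------------------------------------------------------------
# map_read_starts
# ---------------------------------------------------------------------------

def test_error_free_read_maps_at_its_origin(template_300):
    reads = [Read(id="r", sequence=template_300[20:80])]
    profile = map_read_starts(reads, template_300)
    assert profile.counts[20] == 1
    assert profile.n_mapped == 1 and profile.n_unmapped == 0


def test_random_read_is_unmapped(template_300):
    reads = [Read(id="r", sequence=random_dna(60, seed=77))]
    profile = map_read_starts(reads, template_300)
    assert profile.n_mapped == 0 and profile.n_unmapped == 1


def test_short_read_is_unmapped(template_300):
    profile = map_read_starts([Read(id="r", sequence="ACGTACGT")], template_300)
    assert profile.n_unmapped == 1


def test_mapped_profile_equals_generator_start_tally(template_300):
    """With no substitution errors, the mapped start profile reproduces the
    generator's own start histogram exactly."""
    params = RaceSimParams(
        template=template_300, true_sites=[(100, 0.7), (150, 0.3)], n_reads=5000,
        jitter_sd=2.0, background_rate=0.0, subst_error=0.0, seed=21,
    )
    reads, truth = simulate_race_reads(params)
    trimmed, n_untrimmed = trim_adapter(reads, DEFAULT_RACE_ADAPTER, 0)
    assert n_untrimmed == 0
    profile = map_read_starts(trimmed, template_300)
    assert profile.n_unmapped == 0
    assert profile.counts.tolist() == truth.truth["start_histogram"]


def test_read_accounting_conservation(template_300):
    """mapped + unmapped + untrimmed equals the input read count on a noisy run."""
    params = RaceSimParams(
        template=template_300, true_sites=[(120, 1.0)], n_reads=3000,
        jitter_sd=1.0, background_rate=0.1, subst_error=0.01, seed=22,
    )
    reads, _ = simulate_race_reads(params)
    trimmed, n_untrimmed = trim_adapter(reads, DEFAULT_RACE_ADAPTER, 1)
    profile = map_read_starts(trimmed, template_300)
    profile.n_untrimmed = n_untrimmed
    assert profile.n_total == len(reads)
    assert profile.counts.sum() == profile.n_mapped


# ---------------------------------------------------------------------------
# call_start_sites
# ---------------------------------------------------------------------------

def test_unanimous_starts_give_clear_call():
    counts = np.zeros(100, dtype=int)
    counts[20] = 100
    call = call_start_sites(_profile(counts))
    assert call.classification == "clear"
    assert call.sites == [(20, 1.0)]


def test_dominant_peak_over_uniform_background_is_clear():
    counts = np.zeros(300, dtype=int)
    counts[20] = 60
    spread = np.arange(50, 290, 6)  # 40 isolated background positions
    counts[spread] = 1
    call = call_start_sites(_profile(counts))
    assert call.classification == "clear"
    assert call.sites[0] == (20, 0.6)


def test_three_comparable_peaks_are_multiple():
    counts = np.zeros(300, dtype=int)
    counts[[50, 150, 250]] = [40, 35, 25]
    call = call_start_sites(_profile(counts))
    assert call.classification == "multiple"
    assert [p for p, _f in call.sites] == [50, 150, 250]
    assert [f for _p, f in call.sites] == [0.40, 0.35, 0.25]


def test_low_coverage_forces_none():
    counts = np.zeros(100, dtype=int)
    counts[20] = 49
    call = call_start_sites(_profile(counts), min_mapped=50)
    assert call.classification == "none"
    assert call.sites == []
    assert call.fallback_longest_start == 20


def test_all_zero_profile_is_none_with_empty_sites():
    call = call_start_sites(_profile(np.zeros(100, dtype=int)))
    assert call.classification == "none"
    assert call.sites == [] and call.fallback_longest_start is None


def test_fallback_is_five_prime_most_nonzero_position():
    counts = np.zeros(100, dtype=int)
    counts[7] = 1
    counts[20] = 99
    call = call_start_sites(_profile(counts))
    assert call.fallback_longest_start == 7


def test_tied_peaks_prefer_smaller_coordinate():
    counts = np.zeros(100, dtype=int)
    counts[[30, 60]] = 50
    call = call_start_sites(_profile(counts))
    assert call.classification == "multiple"
    assert call.sites[0][0] == 30


def test_dominant_fraction_never_increases_with_background(template_300):
    """Raising the background rate cannot raise the dominant-site fraction in
    expectation (averaged over seeds)."""
    means = []
    for bg in (0.0, 0.2, 0.4):
        fracs = []
        for seed in range(5):
            params = RaceSimParams(
                template=template_300, true_sites=[(120, 1.0)], n_reads=2000,
                jitter_sd=1.0, background_rate=bg, subst_error=0.0, seed=30 + seed,
            )
            reads, _ = simulate_race_reads(params)
            trimmed, _n = trim_adapter(reads, DEFAULT_RACE_ADAPTER, 1)
            call = call_start_sites(map_read_starts(trimmed, template_300))
            fracs.append(call.sites[0][1])
        means.append(np.mean(fracs))
    assert means[0] >= means[1] >= means[2]


def test_appending_sequence_three_prime_of_guide_changes_no_call(template_300):
    """The caller only reads 5' structure: 3' padding cannot change a call."""
    params = RaceSimParams(
        template=template_300, true_sites=[(120, 1.0)], n_reads=2000,
        jitter_sd=1.0, background_rate=0.05, subst_error=0.0, seed=31,
    )
    reads, _ = simulate_race_reads(params)
    trimmed, _n = trim_adapter(reads, DEFAULT_RACE_ADAPTER, 1)
    call_plain = call_start_sites(map_read_starts(trimmed, template_300))
    padded = template_300 + random_dna(100, seed=32)
    call_padded = call_start_sites(map_read_starts(trimmed, padded))
    assert call_plain.classification == call_padded.classification
    assert call_plain.sites == call_padded.sites


# ---------------------------------------------------------------------------
# annotate_scaffold
# ---------------------------------------------------------------------------

def _locus(template: str, guide_start: int, guide_len: int = 20) -> LocusRecord:
    return LocusRecord(
        id="locus", sequence=template, orf_span=(0, guide_start),
        scaffold_span=(0, guide_start),
        guide_span=(guide_start, guide_start + guide_len),
    )


def test_processed_species_of_126_nt_gives_106_nt_scaffold():
    """A processed species of 126 nt with a 20-nt guide leaves a 106-nt
    scaffold between the called start and the RE boundary."""
    template = random_dna(400, seed=40)
    guide_start, guide_len = 326, 20
    called_start = guide_start - (126 - guide_len)
    call = StartSiteCall(classification="clear", sites=[(called_start, 0.95)],
                         fallback_longest_start=called_start)
    ann = annotate_scaffold(call, _locus(template, guide_start), guide_len=guide_len)
    assert ann.end - ann.start == 106
    assert (ann.end - ann.start) + guide_len == 126


def test_call_just_before_boundary_gives_length_one_scaffold():
    template = random_dna(100, seed=41)
    call = StartSiteCall(classification="clear", sites=[(59, 1.0)],
                         fallback_longest_start=59)
    ann = annotate_scaffold(call, _locus(template, 60))
    assert (ann.start, ann.end) == (59, 60)


def test_start_beyond_boundary_is_an_error():
    template = random_dna(100, seed=42)
    call = StartSiteCall(classification="clear", sites=[(60, 1.0)],
                         fallback_longest_start=60)
    with pytest.raises(ValueError, match="beyond RE boundary"):
        annotate_scaffold(call, _locus(template, 60))


def test_fallback_start_used_when_no_clear_site():
    template = random_dna(100, seed=43)
    call = StartSiteCall(classification="none", sites=[], fallback_longest_start=10)
    ann = annotate_scaffold(call, _locus(template, 60))
    assert ann.start == 10 and ann.score is None


def test_annotation_start_equals_planted_site_on_noise_free_reads(template_300):
    params = RaceSimParams(
        template=template_300, true_sites=[(120, 1.0)], n_reads=500,
        jitter_sd=0.0, background_rate=0.0, subst_error=0.0, seed=44,
    )
    reads, _ = simulate_race_reads(params)
    trimmed, _n = trim_adapter(reads, DEFAULT_RACE_ADAPTER, 0)
    call = call_start_sites(map_read_starts(trimmed, template_300))
    ann = annotate_scaffold(call, _locus(template_300, 260))
    assert ann.start == 120
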