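"""Isotope shifts, pair matching, ratio orientation, gel sections and the
fragment/abundance classifier."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apofrag.formats_io import RunConfig, packaged_quant_table
from apofrag.silac_quant import (
    DOWNREGULATED,
    FRAGMENTED,
    UNCHANGED,
    UPREGULATED,
    Peak,
    QuantEntry,
    assign_gel_section,
    classify_protein,
    classify_table,
    label_mass_shift,
    match_pairs,
    nominal_shifts,
    pair_ratio,
    replicate_concordance,
)


def entry(ratio=2.0, mwcal=40.0, lo=35.0, hi=45.0, capped=False, acc="P1",
          orientation="forward"):
    return QuantEntry(
        accession=acc, gene="G", n_unique_peptides=1,
        ratio_apoptotic_live=ratio, capped=capped, mwcal=mwcal,
        mwexp_lo=lo, mwexp_hi=hi, orientation=orientation,
    )


# ---------------------------------------------------------------- mass shifts

@pytest.mark.parametrize(
    "n_lys,n_arg,printed",
    [(1, 0, 6.02), (0, 1, 10.01), (2, 0, 12.04), (1, 1, 16.03), (0, 2, 20.02)],
)
def test_label_shift_matches_printed_values(n_lys, n_arg, printed):
    assert round(label_mass_shift(n_lys, n_arg), 2) == printed


def test_label_shift_additivity_up_to_three():
    for a, b, c, d in itertools.product(range(4), repeat=4):
        if (a + c) == 0 and (b + d) == 0:
            continue
        if (a, b) == (0, 0) or (c, d) == (0, 0):
            continue
        assert label_mass_shift(a + c, b + d) == pytest.approx(
            label_mass_shift(a, b) + label_mass_shift(c, d)
        )


def test_label_shift_rejects_unlabeled():
    with pytest.raises(ValueError):
        label_mass_shift(0, 0)


# ---------------------------------------------------------------- matching

def brute_force_match(peaks, tolerance):
    """Exhaustive optimum: max number of disjoint admissible pairs, then
    minimal total |difference - nominal|."""
    shifts = nominal_shifts().values()
    admissible = []
    for i, j in itertools.combinations(range(len(peaks)), 2):
        diff = abs(peaks[j].mz - peaks[i].mz)
        err = min(abs(diff - s) for s in shifts)
        if err <= tolerance:
            admissible.append((i, j, err))
    best = (0, 0.0)
    best_sets = [frozenset()]
    for r in range(len(admissible), 0, -1):
        for combo in itertools.combinations(admissible, r):
            used = [k for i, j, _ in combo for k in (i, j)]
            if len(used) != len(set(used)):
                continue
            score = (r, -sum(e for *_, e in combo))
            if score > best:
                best = score
                best_sets = [frozenset((i, j) for i, j, _ in combo)]
    return best[0]


def test_match_pairs_exact_shift():
    pairs = match_pairs([Peak(1000.00, 5.0), Peak(1006.02, 3.0)], 0.05)
    assert len(pairs) == 1 and pairs[0].shift_class == "K1"


def test_match_pairs_no_admissible_shift():
    assert match_pairs([Peak(1000.00, 5.0), Peak(1003.00, 3.0)], 0.05) == []


def test_match_pairs_consumed_peak_not_reused():
    peaks = [Peak(1000.00, 1.0), Peak(1006.02, 1.0), Peak(1010.01, 1.0)]
    pairs = match_pairs(peaks, 0.05)
    assert [(p.light_mz, p.heavy_mz, p.shift_class) for p in pairs] == [
        (1000.00, 1006.02, "K1")
    ]


def test_match_pairs_rejects_bad_tolerance():
    with pytest.raises(ValueError):
        match_pairs([Peak(1000.0, 1.0)], -0.1)


@given(
    st.lists(st.floats(min_value=800.0, max_value=3900.0), min_size=1,
             max_size=4, unique=True),
    st.data(),
)
@settings(max_examples=40, deadline=None)
def test_match_pairs_equals_brute_force_on_separated_spectra(bases, data):
    """Peak lists built from well-separated base peaks, some with a heavy
    partner at a nominal shift: greedy matching must find the optimum."""
    shifts = list(nominal_shifts().values())
    bases = sorted(bases)
    if any(b - a < 50 for a, b in zip(bases, bases[1:])):
        return  # enforce separation so pairs cannot chain
    peaks = []
    for b in bases:
        peaks.append(Peak(b, 1.0))
        if data.draw(st.booleans()):
            s = data.draw(st.sampled_from(shifts))
            jitter = data.draw(st.floats(min_value=-0.04, max_value=0.04))
            peaks.append(Peak(b + s + jitter, 1.0))
    got = match_pairs(peaks, 0.05)
    assert len(got) == brute_force_match(peaks, 0.05)
    used = [mz for p in got for mz in (p.light_mz, p.heavy_mz)]
    assert len(used) == len(set(used))


def test_match_pairs_stable_under_permutation():
    peaks = [Peak(1000.0, 1.0), Peak(1006.02, 2.0), Peak(1200.0, 1.0),
             Peak(1210.01, 4.0)]
    fwd = match_pairs(peaks, 0.05)
    rev = match_pairs(list(reversed(peaks)), 0.05)
    assert fwd == rev


# ---------------------------------------------------------------- ratios

def test_pair_ratio_forward():
    assert pair_ratio(200, 100, "forward") == (2.0, False)


def test_pair_ratio_reverse_inverts_channels():
    assert pair_ratio(100, 200, "reverse") == (2.0, False)


def test_pair_ratio_missing_live_channel_caps():
    assert pair_ratio(500, 0, "forward", cap=100) == (100, True)


def test_pair_ratio_orientation_symmetry():
    for h, l in [(3.0, 1.5), (10.0, 0.1), (7.0, 7.0)]:
        assert pair_ratio(h, l, "forward") == pair_ratio(l, h, "reverse")


def test_pair_ratio_both_zero_is_error():
    with pytest.raises(ValueError):
        pair_ratio(0, 0, "forward")


# ---------------------------------------------------------------- gel sections

def test_assign_gel_section_containment():
    assert assign_gel_section(7.5, [5, 10, 15]) == (1, 5, 10)


def test_assign_gel_section_half_open_boundary():
    assert assign_gel_section(10.0, [5, 10, 15]) == (2, 10, 15)


def test_assign_gel_section_below_bottom_maps_to_lowest_band():
    assert assign_gel_section(3.0, [5, 10, 15]) == (1, 5, 10)


def test_assign_gel_section_above_top_is_error():
    with pytest.raises(ValueError):
        assign_gel_section(300.0, [5, 10, 15])


def test_intact_actin_lands_above_observed_low_band(config):
    # a 41.793 kDa intact protein cannot sit in the 5-10 kDa band
    _, lo, _ = assign_gel_section(41.793, config.gel_section_boundaries)
    assert lo > 10


# ---------------------------------------------------------------- classifier

def test_classify_published_fragment_row():
    e = entry(ratio=3.5849, mwcal=51.854, lo=15, hi=20, acc="P53634")
    assert classify_protein(e).label == FRAGMENTED


def test_classify_mw_rule_dominates_near_unity_ratio():
    e = entry(ratio=1.01, mwcal=35.974, lo=5, hi=10, acc="Q8NGV7")
    assert classify_protein(e).label == FRAGMENTED


def test_classify_upregulated():
    assert classify_protein(entry(ratio=3.0)).label == UPREGULATED


def test_classify_downregulated():
    assert classify_protein(entry(ratio=0.3)).label == DOWNREGULATED


def test_classify_unchanged():
    assert classify_protein(entry(ratio=1.2)).label == UNCHANGED


def test_classify_low_mw_but_apoptotic_depleted_is_not_fragment():
    e = entry(ratio=0.3, mwcal=40.0, lo=5, hi=10)
    assert classify_protein(e).label == DOWNREGULATED


@given(st.floats(min_value=1.01, max_value=99.0))
@settings(max_examples=30, deadline=None)
def test_fragment_call_insensitive_to_ratio_threshold_crossing(ratio):
    # flipping the ratio across the up-threshold never changes a FRAGMENTED call
    e = entry(ratio=ratio, mwcal=40.0, lo=5, hi=10)
    assert classify_protein(e).label == FRAGMENTED


def test_every_entry_gets_exactly_one_label(config):
    for e in packaged_quant_table("forward") + packaged_quant_table("reverse"):
        call = classify_protein(e, config)
        assert call.label in (FRAGMENTED, UPREGULATED, DOWNREGULATED, UNCHANGED)


# ---------------------------------------------------------------- concordance

def test_replicate_concordance_on_published_tables():
    fwd = classify_table(packaged_quant_table("forward"))
    rev = classify_table(packaged_quant_table("reverse"))
    assert replicate_concordance(fwd, rev) == {
        "P53634", "P63261", "Q8NGV7", "Q8IZ41", "Q86UE4", "P07602",
    }


def test_replicate_concordance_disjoint_and_idempotent():
    fwd = classify_table([entry(ratio=3.0, mwcal=40, lo=5, hi=10, acc="A")])
    rev = classify_table(
        [entry(ratio=3.0, mwcal=40, lo=5, hi=10, acc="B", orientation="reverse")]
    )
    assert replicate_concordance(fwd, rev) == set()
    assert replicate_concordance(fwd, fwd) == {"A"}


def test_replicate_concordance_rejects_duplicates():
    fwd = classify_table(
        [entry(acc="A", mwcal=40, lo=5, hi=10), entry(acc="A", mwcal=40, lo=5, hi=10)]
    )
    with pytest.raises(ValueError):
        replicate_concordance(fwd, [])
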