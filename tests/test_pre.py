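import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmrmap.errors import (ConfigurationError, NormalizationError,
                           ValidationError)
from nmrmap.io_formats import ResidueID
from nmrmap.pre import (PRERecord, classify_pre_sites, distance_to_pre,
                        normalize_pre, pre_to_distance,
                        records_from_peaklists, restraint_from_pre)
from nmrmap.synthetic import gen_pre_dataset

LABEL = (ResidueID(number=1, aa="C"), "N")


def _rec(num, raw, status="ok"):
    return PRERecord(residue=ResidueID(number=num), i_para=raw, i_dia=1.0,
                     raw_ratio=raw, status=status)


# --- normalization ----------------------------------------------------------

def test_identity_normalization():
    recs = [_rec(i, 1.0) for i in range(1, 6)]
    alpha, recs = normalize_pre(recs, reference=range(1, 6))
    assert alpha == pytest.approx(1.0)
    assert all(r.pre == pytest.approx(1.0) for r in recs)


def test_explicit_reference_arithmetic():
    recs = [_rec(1, 2.0), _rec(2, 2.0), _rec(3, 1.0),
            _rec(4, 2.0), _rec(5, 2.0)]
    alpha, recs = normalize_pre(recs, reference=[1, 2, 4, 5])
    assert alpha == pytest.approx(0.5)
    assert [r.pre for r in recs] == pytest.approx([1.0, 1.0, 0.5, 1.0, 1.0])
    assert [r.in_reference for r in recs] == [True, True, False, True, True]


def test_reference_mean_is_exactly_one():
    rng = np.random.default_rng(0)
    recs = [_rec(i, r) for i, r in enumerate(rng.uniform(0.9, 1.4, 30), 1)]
    alpha, recs = normalize_pre(recs, reference=range(1, 31))
    assert np.mean([r.pre for r in recs if r.in_reference]) == pytest.approx(
        1.0, abs=1e-15)


def test_missing_reference_residues_named():
    recs = [_rec(i, 1.0) for i in range(1, 6)]
    with pytest.raises(NormalizationError, match=r"\[7, 9\]"):
        normalize_pre(recs, reference=[1, 2, 7, 9])


def test_normalization_is_idempotent():
    rng = np.random.default_rng(1)
    raw = rng.uniform(0.5, 1.5, 20)
    recs = [_rec(i, r) for i, r in enumerate(raw, 1)]
    alpha1, recs = normalize_pre(recs, reference=range(1, 21))
    renorm = [_rec(i + 1, recs[i].pre) for i in range(20)]
    alpha2, _ = normalize_pre(renorm, reference=range(1, 21))
    assert alpha2 == pytest.approx(1.0)


def test_auto_reference_finds_distant_residues():
    # 20 distant residues (raw 1.25) and 5 strongly attenuated ones
    recs = [_rec(i, 1.25) for i in range(1, 21)]
    recs += [_rec(i, 0.2) for i in range(21, 26)]
    alpha, recs = normalize_pre(recs, reference="auto")
    assert alpha == pytest.approx(0.8)
    assert all(r.in_reference for r in recs[:20])
    assert not any(r.in_reference for r in recs[20:])


def test_too_few_records_refused():
    with pytest.raises(NormalizationError):
        normalize_pre([_rec(1, 1.0)])


# --- calibration ------------------------------------------------------------

@pytest.mark.parametrize("pre, d", [(0.0, 12.0), (0.5, 21.0), (1.0, 30.0),
                                    (1.4, 30.0)])
def test_linear_calibration(pre, d):
    assert pre_to_distance(pre) == pytest.approx(d)


def test_negative_pre_rejected():
    with pytest.raises(ValidationError):
        pre_to_distance(-0.01)


@given(st.floats(min_value=12.0, max_value=30.0))
@settings(max_examples=200, deadline=None)
def test_calibration_round_trip(d):
    assert pre_to_distance(distance_to_pre(d)) == pytest.approx(d, abs=1e-9)


# --- restraint rules --------------------------------------------------------

def _normalized(num, pre, status="ok"):
    r = _rec(num, pre, status=status)
    r.pre = pre
    return r


@pytest.mark.parametrize("pre, interval", [
    (0.0, (1.8, 12.0)),
    (0.4, (12.0, 22.2)),
    (0.79, (12.0, pytest.approx(12 + 18 * 0.79 + 3))),
])
def test_restraint_branches(pre, interval):
    r = restraint_from_pre(_normalized(204, pre), LABEL)
    assert (r.lower, r.upper) == (pytest.approx(interval[0]),
                                  pytest.approx(interval[1]))
    assert r.site_b[0].number == 204


@pytest.mark.parametrize("pre", [0.8, 0.95, 1.0, 1.3])
def test_weak_pre_is_unrestrained(pre):
    assert restraint_from_pre(_normalized(204, pre), LABEL) is None


def test_disappeared_peak_gets_contact_restraint():
    r = restraint_from_pre(_normalized(10, 0.0, status="disappeared"), LABEL)
    assert (r.lower, r.upper) == (1.8, 12.0)


def test_unnormalized_record_refused():
    with pytest.raises(ValidationError):
        restraint_from_pre(_rec(1, 0.5), LABEL)


@given(st.floats(min_value=0.0, max_value=0.799))
@settings(max_examples=100, deadline=None)
def test_restraint_bounds_always_valid(pre):
    r = restraint_from_pre(_normalized(50, pre), LABEL)
    assert 1.8 <= r.lower <= r.upper <= 33.0


# --- site classification ----------------------------------------------------

CUTOFFS = [(1, 182, 0.88), (183, 352, 0.70)]


@pytest.mark.parametrize("num, pre, flagged", [
    (100, 0.85, True),    # below the N-terminal-region cutoff
    (200, 0.85, False),   # above the C-terminal-region cutoff
    (100, 0.88, False),   # exactly at the cutoff: strict inequality
    (200, 0.69, True),
])
def test_region_specific_cutoffs(num, pre, flagged):
    out = classify_pre_sites([_normalized(num, pre)], cutoffs=CUTOFFS)
    assert (num in out) == flagged


def test_residue_outside_cutoff_ranges_is_a_config_error():
    with pytest.raises(ConfigurationError):
        classify_pre_sites([_normalized(400, 0.5)], cutoffs=CUTOFFS)


def test_classification_grouped_by_domain(sis1_domains):
    recs = [_normalized(100, 0.5), _normalized(200, 0.5)]
    out = classify_pre_sites(recs, cutoffs=CUTOFFS, domains=sis1_domains)
    assert out == {"GF": [100], "CTDI": [200]}


# --- end to end on synthetic data ------------------------------------------

def test_near_label_residues_get_intervals_containing_truth():
    """True distance < 12 A -> [1.8, 12] restraint covering the truth in >= 95%
    of noisy replicates at 2% intensity noise."""
    distances = {n: 40.0 for n in range(1, 41)}
    near = {5: 6.0, 10: 9.5, 15: 11.5}
    distances.update(near)
    covered = total = 0
    for seed in range(20):
        para, dia, truth = gen_pre_dataset(seed, distances, alpha_true=0.8,
                                           noise_frac=0.02)
        recs = records_from_peaklists(para, dia)
        _, recs = normalize_pre(recs, reference="auto")
        for r in recs:
            num = r.residue.number
            if num not in near:
                continue
            total += 1
            restraint = restraint_from_pre(r, LABEL)
            if restraint and restraint.lower <= near[num] <= restraint.upper:
                covered += 1
    assert covered / total >= 0.95


def test_mid_range_distances_recovered_through_the_pipeline():
    distances = {n: 40.0 for n in range(1, 31)}
    distances[3] = 21.0  # true PRE 0.5
    para, dia, truth = gen_pre_dataset(11, distances, alpha_true=0.8,
                                       noise_frac=0.0)
    recs = records_from_peaklists(para, dia)
    alpha, recs = normalize_pre(recs, reference="auto")
    assert alpha == pytest.approx(0.8, rel=1e-9)
    (rec3,) = [r for r in recs if r.residue.number == 3]
    assert pre_to_distance(rec3.pre) == pytest.approx(21.0, abs=1e-9)
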