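"""Empirical quality, concordance MSE, cycle/insert/coverage tables."""

import math

import numpy as np
import pandas as pd
import pytest

from alnqc import (
    KnownSiteMask,
    QcAccumulator,
    ReadFilterPolicy,
    ReferenceGenome,
    concordance_table,
    coverage_summary,
    cycle_table,
    empirical_quality,
    insert_summary,
    quality_mse,
)
from alnqc.metrics import QualityConcordanceTable
from alnqc.pipeline import scan_file
from alnqc.simulate import SimulationParams, simulate_dataset

from conftest import make_read

POLICY = ReadFilterPolicy()
MASK = KnownSiteMask()


# -- empirical_quality ------------------------------------------------------

@pytest.mark.parametrize(
    "matches,mismatches,expect",
    [(900, 100, 10.0), (999, 1, 30.0), (0, 10, 0.0), (90, 10, 10.0)],
)
def test_empirical_quality_closed_form(matches, mismatches, expect):
    assert empirical_quality(matches, mismatches) == pytest.approx(expect)


def test_zero_mismatches_returns_censoring_ceiling():
    assert empirical_quality(100, 0, ceiling=41.0) == 41.0


def test_empirical_quality_undefined_without_bases():
    with pytest.raises(ValueError):
        empirical_quality(0, 0)


def test_empirical_quality_strictly_decreasing_in_mismatches():
    total = 10_000
    vals = [empirical_quality(total - mm, mm) for mm in range(1, 200)]
    assert all(a > b for a, b in zip(vals, vals[1:]))


def test_empirical_quality_recovers_planted_error_rate():
    """Binomial simulation oracle: plant epsilon = 0.01 at 1e6 bases."""
    rng = np.random.default_rng(123)
    mm = int(rng.binomial(1_000_000, 0.01))
    q = empirical_quality(1_000_000 - mm, mm)
    assert q == pytest.approx(20.0, abs=0.2)


# -- concordance + MSE ------------------------------------------------------

def _table(rows):
    df = pd.DataFrame(rows, columns=["reported_q", "n_bases", "empirical_q"])
    df["n_matches"] = df["n_bases"]
    df["n_mismatches"] = 0
    df["censored"] = False
    return QualityConcordanceTable(df, ceiling=94.0)


def test_mse_zero_for_perfect_calibration():
    t = _table([(10, 100, 10.0), (20, 100, 20.0), (30, 100, 30.0)])
    assert quality_mse(t) == 0.0


def test_mse_hand_arithmetic_single_row():
    assert quality_mse(_table([(30, 500, 20.0)])) == pytest.approx(100.0)


def test_mse_of_constant_offset_is_offset_squared():
    base = [(10, 300, 10.0), (20, 100, 20.0), (35, 600, 35.0)]
    for delta in (1.5, -4.0):
        shifted = [(q, n, e + delta) for q, n, e in base]
        assert quality_mse(_table(shifted)) == pytest.approx(delta * delta)


def test_mse_weights_rows_by_base_count():
    t = _table([(10, 900, 10.0), (30, 100, 20.0)])  # only q30 off, by 10
    assert quality_mse(t) == pytest.approx(0.1 * 100.0)


def test_mse_requires_an_uncensored_row():
    df = _table([(30, 10, 94.0)]).frame
    df["censored"] = True
    with pytest.raises(ValueError):
        quality_mse(QualityConcordanceTable(df, 94.0))


def test_concordance_table_from_counts():
    ref = ReferenceGenome({"c1": "ACGTACGT"})
    acc = QcAccumulator(ref.lengths)
    acc.add_record(make_read("ACGA", [("M", 4)], quals=30), ref, MASK, POLICY)
    t = concordance_table(acc)
    row = t.frame.iloc[0]
    assert row.reported_q == 30 and row.n_matches == 3 and row.n_mismatches == 1
    assert row.empirical_q == pytest.approx(-10 * math.log10(0.25))
    assert not row.censored


def test_empty_accumulator_gives_empty_table():
    acc = QcAccumulator({"c1": 10})
    assert concordance_table(acc).frame.empty
    assert cycle_table(acc).frame.empty
    assert insert_summary(acc) == {}


def test_calibrated_run_has_much_lower_mse_than_miscalibrated(tmp_path):
    cal = simulate_dataset(
        SimulationParams(genome_bp=30_000, n_pairs=600, seed=31), tmp_path / "cal"
    )
    mis = simulate_dataset(
        SimulationParams(
            genome_bp=30_000, n_pairs=600, seed=31, quality_offset_phred=-10.0
        ),
        tmp_path / "mis",
    )
    mses = {}
    for name, ds in (("cal", cal), ("mis", mis)):
        from alnqc import load_known_sites

        acc = scan_file(ds.sam_path, ds.reference, load_known_sites(ds.known_sites_path))
        mses[name] = quality_mse(concordance_table(acc))
    assert mses["mis"] > 10 * mses["cal"]
    assert mses["mis"] == pytest.approx(100.0, abs=20.0)


# -- cycle table ------------------------------------------------------------

def test_cycle_rows_only_for_observed_cycles():
    ref = ReferenceGenome({"c1": "ACGTACGT"})
    acc = QcAccumulator(ref.lengths)
    acc.add_record(make_read("ACGT", [("M", 4)], quals=25), ref, MASK, POLICY)
    t = cycle_table(acc).frame
    assert list(t["cycle"]) == [1, 2, 3, 4]
    assert (t["mean_reported_q"] == 25.0).all()
    comp = t[["frac_A", "frac_C", "frac_G", "frac_T", "frac_N"]].sum(axis=1)
    assert np.allclose(comp, 1.0)


def test_empirical_quality_declines_when_error_rises_with_cycle(tmp_path):
    # the 30/20/10 step profile plants error rising along the read
    ds = simulate_dataset(
        SimulationParams(genome_bp=30_000, n_pairs=1_000, seed=37), tmp_path
    )
    from alnqc import load_known_sites

    acc = scan_file(ds.sam_path, ds.reference, load_known_sites(ds.known_sites_path))
    t = cycle_table(acc).frame
    L = ds.truth.params.read_length
    first = t[t["cycle"] <= L // 3]["empirical_q"].mean()
    last = t[t["cycle"] > 2 * L // 3]["empirical_q"].mean()
    assert first > last + 5


# -- insert summary ---------------------------------------------------------

def test_degenerate_insert_distribution():
    ref = ReferenceGenome({"c1": "A" * 1000})
    acc = QcAccumulator(ref.lengths)
    for i in range(5):
        acc.add_record(
            make_read("AAAA", [("M", 4)], pos_1based=1 + i, paired=True, proper=True,
                      tlen=300, name=f"p{i}"),
            ref, MASK, POLICY,
        )
    s = insert_summary(acc)["rg1"]
    assert s.mode == 300 and s.mean == 300.0 and s.median == 300.0 and s.sd == 0.0
    assert s.n_pairs == 5 and s.overflow_fraction == 0.0


def test_histogram_stats_match_numpy_on_expanded_sizes():
    ref = ReferenceGenome({"c1": "A" * 5000})
    acc = QcAccumulator(ref.lengths)
    rng = np.random.default_rng(41)
    sizes = rng.integers(100, 700, 500)
    for i, t in enumerate(sizes):
        acc.add_record(
            make_read("AAAA", [("M", 4)], pos_1based=1, paired=True, proper=True,
                      tlen=int(t), name=f"p{i}"),
            ref, MASK, POLICY,
        )
    s = insert_summary(acc)["rg1"]
    assert s.mean == pytest.approx(sizes.mean())
    assert s.sd == pytest.approx(sizes.std())
    assert s.mode == np.bincount(sizes).argmax()


def test_two_read_groups_summarised_independently():
    ref = ReferenceGenome({"c1": "A" * 1000})
    acc = QcAccumulator(ref.lengths)
    for rg, t in (("rgX", 200), ("rgY", 400)):
        acc.add_record(
            make_read("AAAA", [("M", 4)], paired=True, proper=True, tlen=t,
                      read_group=rg, name=rg),
            ref, MASK, POLICY,
        )
    s = insert_summary(acc)
    assert set(s) == {"rgX", "rgY"}
    assert s["rgX"].mean == 200.0 and s["rgY"].mean == 400.0


def test_simulated_normal_insert_moments_recovered(tmp_path):
    ds = simulate_dataset(
        SimulationParams(genome_bp=50_000, n_pairs=2_000, seed=43, n_read_groups=1),
        tmp_path,
    )
    acc = scan_file(ds.sam_path, ds.reference)
    s = insert_summary(acc)["rg1"]
    truth = ds.truth.insert_sizes["rg1"]
    assert s.mean == pytest.approx(truth.mean(), abs=1e-9)  # histogram is exact
    assert s.sd == pytest.approx(truth.std(), abs=1e-9)
    assert s.mean == pytest.approx(300.0, abs=2.5)
    assert s.sd == pytest.approx(30.0, abs=2.0)


# -- coverage ---------------------------------------------------------------

def test_coverage_mean_depth_and_fractions():
    ref = ReferenceGenome({"c1": "A" * 1000})
    acc = QcAccumulator(ref.lengths)
    for i in range(10):
        acc.add_record(
            make_read("A" * 100, [("M", 100)], pos_1based=1 + 50 * i,
                      duplicate=(i % 2 == 1), name=f"r{i}"),
            ref, MASK, POLICY,
        )
    cov = coverage_summary(acc, 1000)
    assert cov.mean_depth == pytest.approx(0.5)  # 5 passing reads x 100 bases
    assert cov.duplicate_fraction == 0.5
    assert cov.mapped_fraction == 1.0
    assert cov.records_seen == 10


def test_coverage_requires_positive_span():
    with pytest.raises(ValueError):
        coverage_summary(QcAccumulator({"c1": 5}), 0)


def test_simulated_depth_near_nominal(tmp_path):
    # 2500 pairs x 200 bases over 100 kb = 5x nominal
    ds = simulate_dataset(SimulationParams(seed=47, duplicate_fraction=0.0), tmp_path)
    acc = scan_file(ds.sam_path, ds.reference)
    cov = coverage_summary(acc, ds.reference.genome_span)
    assert cov.mean_depth == pytest.approx(5.0, rel=0.01)
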