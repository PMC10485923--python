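"""Forward model identities, R-matrix behavior, subsection proposal and
rate optimization on small synthetic problems."""

import math

import numpy as np
import pytest

from hdx2ss._errors import ValidationError
from hdx2ss.hdx_io import KintTable, PeptideRecord, UptakeTable
from hdx2ss.residue_optimizer import (
    OptimizerConfig,
    SubsectionSpec,
    compute_rmatrix,
    exchanging_indices,
    forward_rfu,
    optimize_protein,
    optimize_subsection,
    predict_peptide_rfu,
    propose_subsections,
    read_rates_csv,
    write_rates_csv,
)
from hdx2ss.rfu_correction import correct_table
from hdx2ss.synthetic_fixtures import (
    FixtureConfig,
    make_peptide_map,
    make_protein,
    make_uptake,
)


# ---------------------------------------------------------------------------
# forward model

def test_exchanging_indices_skip_first_two_and_prolines():
    assert exchanging_indices("GASLV", 10, 14) == [12, 13, 14]
    assert exchanging_indices("GAPLP", 10, 14) == [13]
    assert exchanging_indices("PPG", 10, 12) == [12]


def test_half_exchange_at_log_two_over_rate():
    # a single exchanging residue with k_obs * t = ln 2 is exactly half
    # exchanged: RFU = 1 - exp(-ln 2) = 0.5
    kint = KintTable(rates={3: 2.0})  # 1/min
    lnp = {3: 1.0}
    k_obs = 2.0 * math.exp(-1.0)
    t_sec = (math.log(2.0) / k_obs) * 60.0
    rfu = forward_rfu(lnp, kint, "GAS", 1, 3, t_sec)
    assert rfu == pytest.approx(0.5, abs=1e-12)


def test_forward_rfu_is_mean_over_exchanging_residues():
    kint = KintTable(rates={3: 1.0, 4: 1.0})
    lnp = {3: 0.0, 4: 50.0}  # residue 4 effectively frozen
    rfu = forward_rfu(lnp, kint, "GASL", 1, 4, 1e9)
    assert rfu == pytest.approx(0.5, abs=1e-6)


def test_forward_rfu_missing_inputs_raise():
    kint = KintTable(rates={3: 1.0})
    with pytest.raises(ValidationError):
        forward_rfu({}, kint, "GAS", 1, 3, 60.0)
    with pytest.raises(ValidationError):
        forward_rfu({3: 1.0, 4: 1.0}, kint, "GASL", 1, 4, 60.0)
    with pytest.raises(ValidationError):
        forward_rfu({3: 1.0}, kint, "GAP", 1, 3, 60.0)  # no exchanging residues


def test_noise_free_generation_round_trips_through_forward_model(small_protein, small_map):
    cfg0 = FixtureConfig(n_residues=60, seed=1, noise_sd=0.0)
    table = correct_table(make_uptake(small_protein, small_map, cfg=cfg0))
    for rec in table.records:
        for t, corr in rec.rfu_corr.items():
            pred = predict_peptide_rfu(small_protein.lnp_true, small_protein.kint, rec, t)
            assert pred == pytest.approx(corr, abs=1e-12)


# ---------------------------------------------------------------------------
# R-matrix

def test_identical_replicates_score_one(rng):
    base = rng.uniform(0, 14, size=30)
    reps = np.tile(base, (5, 1))
    assert compute_rmatrix(reps) == pytest.approx(1.0)


def test_anticorrelated_replicates_score_zero(rng):
    base = rng.uniform(0, 14, size=30)
    reps = np.stack([base, -base])
    assert compute_rmatrix(reps) == 0.0


def test_independent_replicates_score_near_zero(rng):
    reps = rng.uniform(0, 14, size=(10, 500))
    assert compute_rmatrix(reps) < 0.1


def test_zero_variance_replicate_scores_zero_with_warning(rng, caplog):
    base = rng.uniform(0, 14, size=30)
    reps = np.stack([base, np.full(30, 7.0)])
    with caplog.at_level("WARNING"):
        score = compute_rmatrix(reps)
    assert score == 0.0
    assert any("zero lnP variance" in r.message for r in caplog.records)


def test_rmatrix_input_validation(rng):
    with pytest.raises(ValidationError):
        compute_rmatrix(rng.uniform(size=(1, 30)))
    with pytest.raises(ValidationError):
        compute_rmatrix(rng.uniform(size=(5, 2)))
    with pytest.raises(ValidationError):
        compute_rmatrix(rng.uniform(size=30))


def test_rmatrix_is_bounded(rng):
    for _ in range(20):
        reps = rng.normal(size=(4, 25))
        assert 0.0 <= compute_rmatrix(reps) <= 1.0


# ---------------------------------------------------------------------------
# subsections

def _toy_table(peptides, n=40, seed=5, **fix_kwargs):
    cfg = FixtureConfig(n_residues=n, seed=seed, **fix_kwargs)
    prot = make_protein(cfg)
    table = make_uptake(prot, peptides, cfg=cfg)
    return prot, correct_table(table)


def test_connected_map_yields_single_subsection():
    prot, table = _toy_table([(1, 8), (5, 12), (9, 16), (13, 20)])
    specs = propose_subsections(table)
    assert len(specs) == 1
    assert (specs[0].start, specs[0].end) == (1, 20)


def test_coverage_gap_splits_subsections():
    prot, table = _toy_table([(1, 8), (5, 12), (20, 27), (24, 31)])
    specs = propose_subsections(table)
    assert [(s.start, s.end) for s in specs] == [(1, 12), (20, 31)]


def test_abutting_unspanned_junction_splits_subsections():
    # peptides meet at 12|13 but none spans the boundary
    prot, table = _toy_table([(1, 8), (5, 12), (13, 20), (17, 24)])
    specs = propose_subsections(table)
    assert [(s.start, s.end) for s in specs] == [(1, 12), (13, 24)]


def test_subsection_validation_rejects_foreign_and_sparse_peptides():
    prot, table = _toy_table([(1, 8), (5, 12)])
    with pytest.raises(ValidationError):
        SubsectionSpec(1, 12, [("NOPE", 1, 4)]).validate(table)
    with pytest.raises(ValidationError):
        spec = SubsectionSpec(1, 40, [rec.key() for rec in table.records])
        spec.validate(table)  # 12/40 residues covered < 80%


def test_optimizer_config_validation():
    with pytest.raises(ValidationError):
        OptimizerConfig(n_replicates=1)
    with pytest.raises(ValidationError):
        OptimizerConfig(window=1)
    with pytest.raises(ValidationError):
        OptimizerConfig(refine_passes=-1)


# ---------------------------------------------------------------------------
# optimization

def test_optimizer_recovers_rates_on_small_protein():
    cfg = FixtureConfig(n_residues=40, seed=2)
    prot = make_protein(cfg)
    peps = make_peptide_map(prot, cfg)
    table = correct_table(make_uptake(prot, peps, cfg=cfg))
    model = optimize_protein(table, prot.kint, OptimizerConfig(n_replicates=4, seed=0))
    res = sorted(model.lnp)
    fit = np.array([model.lnp[r] for r in res])
    tru = np.array([prot.lnp_true[r] for r in res])
    assert np.corrcoef(fit, tru)[0, 1] > 0.85
    assert all(0.0 <= v <= 14.0 for v in fit)
    # the three rate columns satisfy lnP = ln(k_int / k_obs)
    for r in res:
        assert model.lnp[r] == pytest.approx(math.log(model.k_int[r] / model.k_obs[r]), abs=1e-9)


def test_optimizer_is_deterministic():
    cfg = FixtureConfig(n_residues=30, seed=4)
    prot = make_protein(cfg)
    peps = make_peptide_map(prot, cfg)
    table = correct_table(make_uptake(prot, peps, cfg=cfg))
    m1 = optimize_protein(table, prot.kint, OptimizerConfig(n_replicates=3, seed=7))
    m2 = optimize_protein(table, prot.kint, OptimizerConfig(n_replicates=3, seed=7))
    assert m1.lnp == m2.lnp
    assert m1.r_matrix == m2.r_matrix


def test_uncorrected_table_raises(small_uptake, small_protein):
    spec = propose_subsections(small_uptake)[0]
    with pytest.raises(ValidationError):
        optimize_subsection(small_uptake, small_protein.kint, spec, OptimizerConfig(n_replicates=2))


def test_split_protein_gets_per_subsection_scores():
    cfg = FixtureConfig(n_residues=60, seed=6, junctions=[30])
    prot = make_protein(cfg)
    peps = make_peptide_map(prot, cfg)
    table = correct_table(make_uptake(prot, peps, cfg=cfg))
    model = optimize_protein(table, prot.kint, OptimizerConfig(n_replicates=3, seed=0))
    assert len(model.r_matrix) == 2
    assert set(model.subsection_of.values()) == {0, 1}
    for score in model.r_matrix.values():
        assert 0.0 <= score <= 1.0


def test_uncovered_residues_are_absent():
    cfg = FixtureConfig(n_residues=60, seed=6, gaps=[(25, 35)])
    prot = make_protein(cfg)
    peps = make_peptide_map(prot, cfg)
    table = correct_table(make_uptake(prot, peps, cfg=cfg))
    model = optimize_protein(table, prot.kint, OptimizerConfig(n_replicates=3, seed=0))
    covered = table.coverage()
    assert all(r in covered for r in model.lnp)
    assert not any(28 <= r <= 32 for r in model.lnp)


def test_rates_csv_round_trip(tmp_path):
    cfg = FixtureConfig(n_residues=30, seed=4)
    prot = make_protein(cfg)
    peps = make_peptide_map(prot, cfg)
    table = correct_table(make_uptake(prot, peps, cfg=cfg))
    model = optimize_protein(table, prot.kint, OptimizerConfig(n_replicates=3, seed=0))
    path = tmp_path / "rates.csv"
    write_rates_csv(model, path)
    again = read_rates_csv(path)
    assert set(again.lnp) == set(model.lnp)
    for r in model.lnp:
        assert again.lnp[r] == pytest.approx(model.lnp[r], abs=1e-9)
        assert again.rmatrix_of_residue(r) == pytest.approx(model.rmatrix_of_residue(r), abs=1e-9)
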