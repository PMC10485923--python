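"""Statistical and structural contracts of the synthetic data generator."""

import numpy as np
import pytest

from hdx2ss._errors import ValidationError
from hdx2ss.pipeline import assemble_features
from hdx2ss.residue_optimizer import exchanging_indices
from hdx2ss.rfu_correction import correct_table
from hdx2ss.structure_labels import classify_secondary_structure, compute_dihedrals
from hdx2ss.synthetic_fixtures import (
    FixtureConfig,
    _signature_runs,
    coverage_fraction,
    make_gated_feature_table,
    make_peptide_map,
    make_protein,
    make_uptake,
)


def test_generation_is_deterministic(small_cfg, small_protein, small_map, small_uptake):
    prot2 = make_protein(small_cfg)
    assert prot2.sequence == small_protein.sequence
    assert prot2.lnp_true == small_protein.lnp_true
    assert make_peptide_map(prot2, small_cfg) == small_map
    up2 = make_uptake(prot2, small_map, cfg=small_cfg)
    for a, b in zip(up2.records, small_uptake.records):
        assert a.exposures == b.exposures


def test_segments_alternate_and_tile(small_protein, small_cfg):
    segs = small_protein.segments
    assert segs[0][0] == 1
    assert segs[-1][1] == small_cfg.n_residues
    for (s1, e1, l1), (s2, e2, l2) in zip(segs, segs[1:]):
        assert s2 == e1 + 1
        assert l2 == 1 - l1


def test_lnp_marginals_match_class_means():
    cfg = FixtureConfig(n_residues=4000, seed=8)
    prot = make_protein(cfg)
    lnp = np.array([prot.lnp_true[r] for r in sorted(prot.lnp_true)])
    lab = np.array([prot.labels_true[r] for r in sorted(prot.lnp_true)])
    assert lnp[lab == 0].mean() == pytest.approx(cfg.helix_lnp_mean, abs=0.15)
    assert lnp[lab == 1].mean() == pytest.approx(cfg.strand_lnp_mean, abs=0.15)
    assert lnp[lab == 0].std() == pytest.approx(cfg.lnp_sd, abs=0.15)
    assert (lnp >= cfg.lnp_bounds[0]).all() and (lnp <= cfg.lnp_bounds[1]).all()


def test_lnp_is_spatially_correlated_within_segments():
    cfg = FixtureConfig(n_residues=4000, seed=8)
    prot = make_protein(cfg)
    pairs = []
    for start, end, lab in prot.segments:
        mean = cfg.helix_lnp_mean if lab == 0 else cfg.strand_lnp_mean
        for r in range(start, end):
            pairs.append((prot.lnp_true[r] - mean, prot.lnp_true[r + 1] - mean))
    a, b = np.array(pairs).T
    rho_hat = np.corrcoef(a, b)[0, 1]
    assert rho_hat == pytest.approx(cfg.lnp_rho, abs=0.05)


def test_structure_matches_protection_truth(small_protein):
    table = classify_secondary_structure(compute_dihedrals(small_protein.backbone))
    agree = [table.labels[r] == small_protein.labels_true[r] for r in table.labels]
    assert np.mean(agree) > 0.95


def test_map_is_contiguous_and_meets_redundancy(small_protein, small_map, small_cfg):
    n = small_cfg.n_residues
    assert coverage_fraction(small_map, n) == 1.0
    depth = sum(e - s + 1 for s, e in small_map) / n
    assert depth >= small_cfg.redundancy
    lo, hi = small_cfg.peptide_length_range
    for s, e in small_map:
        assert e - s + 1 <= hi


def test_degeneracy_breaking_removes_signature_runs(small_protein, small_map):
    runs = _signature_runs(small_protein.sequence, small_map, 1, len(small_protein.sequence))
    assert runs == []


def test_without_breaking_signature_runs_remain():
    cfg = FixtureConfig(n_residues=80, seed=2, break_degeneracies=False)
    prot = make_protein(cfg)
    peps = make_peptide_map(prot, cfg)
    runs = _signature_runs(prot.sequence, peps, 1, 80)
    assert len(runs) > 0


def test_gaps_are_never_covered():
    cfg = FixtureConfig(n_residues=80, seed=2, gaps=[(30, 40)])
    prot = make_protein(cfg)
    peps = make_peptide_map(prot, cfg)
    for s, e in peps:
        assert e < 30 or s > 40


def test_junctions_are_never_spanned():
    cfg = FixtureConfig(n_residues=80, seed=2, junctions=[40])
    prot = make_protein(cfg)
    peps = make_peptide_map(prot, cfg)
    for s, e in peps:
        assert not (s <= 40 < e)


def test_infeasible_redundancy_raises(small_protein):
    cfg = FixtureConfig(n_residues=60, seed=1, redundancy=20.0)
    with pytest.raises(ValidationError):
        make_peptide_map(small_protein, cfg)


def test_uptake_respects_controls_and_noise(small_uptake, small_cfg):
    for rec in small_uptake.records:
        assert rec.rfu_fex == small_cfg.fex
        assert rec.rfu_bex == small_cfg.bex
        for v in rec.exposures.values():
            assert -0.05 <= v <= 1.2


def test_uptake_increases_with_time_when_noise_free(small_protein, small_map):
    cfg0 = FixtureConfig(n_residues=60, seed=1, noise_sd=0.0)
    table = make_uptake(small_protein, small_map, cfg=cfg0)
    for rec in table.records:
        vals = [rec.exposures[t] for t in rec.times]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))


def test_config_validation():
    with pytest.raises(ValidationError):
        FixtureConfig(lnp_sd=0.0)
    with pytest.raises(ValidationError):
        FixtureConfig(lnp_rho=1.0)
    with pytest.raises(ValidationError):
        FixtureConfig(bex=0.05, fex=0.05)
    with pytest.raises(ValidationError):
        make_uptake(make_protein(FixtureConfig(n_residues=20, seed=0)), [(1, 8)], times=(0.0,))


def test_gated_table_shapes_and_gating():
    ft = make_gated_feature_table(n=400, seed=0)
    assert ft.X.shape == (400, 4)
    assert ft.feature_names == ("k_obs", "k_int", "r_matrix", "aa_code")
    r_col = ft.X[:, 2]
    assert set(np.unique(r_col)) == {0.2, 0.9}
    # in the trusted half k_obs separates the classes; in the noisy half it doesn't
    high = r_col == 0.9
    k = np.log(ft.X[:, 0])
    gap_high = abs(k[high & (ft.y == 0)].mean() - k[high & (ft.y == 1)].mean())
    gap_low = abs(k[~high & (ft.y == 0)].mean() - k[~high & (ft.y == 1)].mean())
    assert gap_high > 2.0
    assert gap_low < 1.0


def test_assemble_features_joins_on_common_residues(small_protein, small_corrected):
    from hdx2ss.residue_optimizer import OptimizerConfig, optimize_protein

    model = optimize_protein(small_corrected, small_protein.kint, OptimizerConfig(n_replicates=2, seed=0))
    labels = classify_secondary_structure(
        compute_dihedrals(small_protein.backbone),
        aa_by_residue={i + 1: a for i, a in enumerate(small_protein.sequence)},
    )
    ft = assemble_features(model, labels)
    assert ft.feature_names == ("k_obs", "k_int", "r_matrix", "aa_code")
    assert len(ft) == len(set(model.lnp) & set(labels.labels) & set(labels.aa_code))
    ft_abl = assemble_features(model, labels, drop_features=("r_matrix",))
    assert ft_abl.feature_names == ("k_obs", "k_int", "aa_code")
    assert ft_abl.X.shape[1] == 3
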