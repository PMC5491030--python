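import numpy as np
import pytest

import milieu
from milieu.simulate import (
    ConfigurationError,
    GroupSpec,
    SimulationConfig,
    largest_remainder_sizes,
    planted_increment_config,
)


def test_default_config_group_allocation():
    cfg = milieu.default_study_config()
    assert cfg.n_participants == 211
    sizes = largest_remainder_sizes([g.proportion for g in cfg.groups], 211)
    assert sizes == [92, 50, 64, 5]
    assert abs(sum(g.proportion for g in cfg.groups) - 1.0) < 1e-9
    shifts = [g.engagement_shift for g in cfg.groups]
    assert all(a > b for a, b in zip(shifts, shifts[1:]))
    assert cfg.groups[3].smoker_profile
    assert all(g.lifestyle_conflict < 0 for g in cfg.groups[2:])


def test_largest_remainder_allocates_exactly():
    assert largest_remainder_sizes([0.5, 0.3, 0.2], 10) == [5, 3, 2]
    assert sum(largest_remainder_sizes([1 / 3] * 3, 10)) == 10


def test_generation_is_deterministic(tmp_path):
    cfg = milieu.default_study_config()
    a, _ = milieu.generate_dataset(cfg, seed=3)
    b, _ = milieu.generate_dataset(cfg, seed=3)
    pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
    a.to_csv(pa)
    b.to_csv(pb)
    assert pa.read_bytes() == pb.read_bytes()
    c, _ = milieu.generate_dataset(cfg, seed=4)
    assert not np.array_equal(a.followup_counts.to_numpy(), c.followup_counts.to_numpy())


@pytest.mark.parametrize("seed", [0, 5])
def test_value_ranges_hold(seed):
    raw, _ = milieu.generate_dataset(milieu.default_study_config(), seed=seed)
    for frame in (raw.baseline_counts, raw.followup_counts):
        arr = frame.to_numpy()
        assert (arr >= 0).all() and np.array_equal(arr, np.round(arr))
    cog = raw.cognitions.to_numpy()
    assert cog.min() >= 1.0 and cog.max() <= 7.0


def test_degenerate_configs_rejected():
    with pytest.raises(ConfigurationError, match="size 0"):
        SimulationConfig(
            n_participants=100,
            groups=[GroupSpec("a", 0.999), GroupSpec("b", 0.001)],
        ).validate()
    with pytest.raises(ConfigurationError, match="4 x"):
        SimulationConfig(n_participants=7, groups=[GroupSpec("a", 0.5), GroupSpec("b", 0.5)]).validate()
    with pytest.raises(ConfigurationError, match="sum"):
        SimulationConfig(n_participants=100, groups=[GroupSpec("a", 0.6), GroupSpec("b", 0.6)]).validate()


def test_engagement_shift_monotone_in_expected_index():
    """Raising a group's engagement shift raises its expected health index."""
    means = []
    for shift in (-1.0, 0.5, 2.0):
        cfg = SimulationConfig(
            n_participants=600,
            groups=[GroupSpec("a", 0.5, engagement_shift=shift), GroupSpec("b", 0.5)],
            seed=0,
        )
        raw, truth = milieu.generate_dataset(cfg, seed=11)
        std = milieu.standardize(raw)
        means.append(std.health_index[truth.group_labels == 0].mean())
    assert means[0] < means[1] < means[2]


def test_pure_cognition_signal_yields_high_r2():
    """With noise terms switched (nearly) off and signal only through the
    motivation latent, OLS of the index on the health-cognition block
    approaches a perfect fit."""
    cfg = SimulationConfig(
        n_participants=800,
        groups=[GroupSpec("all", 1.0, cognition_loadings={"health": 1.0, "lifestyle": 0.0})],
        noise_sd=0.02,
        cognition_weight=1.0,
        habit_weight=0.0,
        target_noise_sd=0.02,
        health_noise_sd=0.02,
        count_link="rounded_gaussian",
        count_scale=20.0,  # fine count grid: negligible discretization
        count_mu=100.0,
    )
    raw, _ = milieu.generate_dataset(cfg, seed=2)
    std = milieu.standardize(raw)
    blocks = milieu.assemble_blocks(std)
    X = np.column_stack([np.ones(cfg.n_participants), blocks["health_cognitions"].to_numpy()])
    y = std.health_index.to_numpy()
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r2 = 1 - ((y - X @ beta) ** 2).mean() / y.var()
    assert r2 > 0.97


def test_no_conflict_means_no_lifestyle_signal():
    """With lifestyle_conflict = 0 and no nonlinearity, lifestyle activity
    counts are unrelated to the index once cognitions are controlled."""
    cfg = SimulationConfig(
        n_participants=4000,
        groups=[GroupSpec("all", 1.0, lifestyle_conflict=0.0)],
        nonlinearity_strength=0.0,
    )
    raw, truth = milieu.generate_dataset(cfg, seed=5)
    std = milieu.standardize(raw)
    blocks = milieu.assemble_blocks(std)
    y = std.health_index.to_numpy()
    c = truth.components["c"].to_numpy()
    # residualize on the motivation latent (what cognitions measure)
    def resid(v):
        b = np.polyfit(c, v, 1)
        return v - np.polyval(b, c)
    ry = resid(y)
    for col in ("act_go_clubbing", "act_visit_friend", "act_read_for_pleasure"):
        r = np.corrcoef(resid(blocks["lifestyle_activities"][col].to_numpy()), ry)[0, 1]
        assert abs(r) < 0.05


def test_planted_increments_recovered_by_latent_oracle():
    """Hierarchical OLS on the true latent components recovers the planted
    incremental variance fractions 0.18 / 0.24 / 0.29."""
    def r2(Xcols, y):
        X = np.column_stack([np.ones(len(y))] + Xcols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return 1 - ((y - X @ beta) ** 2).mean() / y.var()

    incs = []
    for seed in range(5):
        raw, truth = milieu.generate_dataset(planted_increment_config(2000), seed=seed)
        std = milieu.standardize(raw)
        y = std.health_index.to_numpy()
        comp = truth.components
        r1 = r2([comp["c"].to_numpy()], y)
        r13 = r2([comp[k].to_numpy() for k in ("c", "s")], y)
        r134 = r2([comp[k].to_numpy() for k in ("c", "s", "b")], y)
        incs.append((r1, r13 - r1, r134 - r13))
    mean = np.asarray(incs).mean(axis=0)
    truth_vals = np.asarray([0.18, 0.24, 0.29])
    assert np.all(np.abs(mean - truth_vals) <= 0.05)
    assert milieu.generate_dataset(planted_increment_config(200), seed=0)[1].planted_increments is not None
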