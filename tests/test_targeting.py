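"""FSEOF scoring and scanning, plus the feature-importance pipeline."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from pcsec.targeting import (
    ScoreParams,
    fseof_scan,
    make_cassette_grid,
    priority_score,
    select_targets,
)


def brute_force_score(traj, ref, is_subunit, has_paralog, p=None):
    """Straight-line reimplementation of the scoring rules (the oracle)."""
    p = p or ScoreParams()
    traj = np.asarray(traj, float)
    scale = np.abs(traj).max()
    q = np.round(traj / scale / p.quantize) * p.quantize * scale if scale > 0 else traj * 0
    rho = stats.spearmanr(np.arange(len(q)), q).statistic if len(set(q)) > 1 else 0.0
    strictly_up = rho > 1 - 1e-12 and all(b > a for a, b in zip(q, q[1:]))
    strictly_down = rho < -1 + 1e-12 and all(b < a for a, b in zip(q, q[1:]))
    if strictly_down:
        return -1
    if not strictly_up:
        return 0
    score = 1
    fold_ok = q[0] <= 0 or q[-1] / q[0] >= p.fold_gate
    if not fold_ok:
        return score
    score = 2
    if not (ref > 0 and q[-1] > 0 and max(q[-1] / ref, ref / q[-1]) <= p.paxdb_band):
        return score
    score = 3
    if not is_subunit and not has_paralog:
        score = 4
    return score


class TestPriorityScore:
    def test_full_chain_reaches_four(self):
        traj = [1.0, 1.1, 1.2, 1.35]
        assert priority_score(traj, 1.0, False, False) == 4

    def test_fold_gate_blocks_at_one(self):
        traj = [1.0, 1.03, 1.06, 1.1]
        assert priority_score(traj, 1.0, False, False) == 1

    def test_decreasing_is_downregulation(self):
        assert priority_score([3.0, 2.0, 1.0], 1.0, False, False) == -1

    def test_flat_or_nonmonotone_is_zero(self):
        assert priority_score([1.0, 1.0, 1.0], 1.0, False, False) == 0
        assert priority_score([1.0, 2.0, 1.5], 1.0, False, False) == 0

    def test_subunit_or_paralog_capped_at_three(self):
        traj = [1.0, 1.2, 1.5]
        assert priority_score(traj, 1.2, True, False) == 3
        assert priority_score(traj, 1.2, False, True) == 3

    def test_band_gate_blocks_at_two(self):
        traj = [1.0, 1.3, 2.0]
        assert priority_score(traj, 1000.0, False, False) == 2

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            priority_score([1.0, np.nan, 2.0], 1.0, False, False)

    def test_oracle_equivalence_1000_random(self):
        """Scorer agrees exactly with the brute-force reimplementation."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(3, 9))
            kind = rng.integers(0, 4)
            if kind == 0:
                traj = np.sort(rng.uniform(0.1, 2.0, n))
            elif kind == 1:
                traj = np.sort(rng.uniform(0.1, 2.0, n))[::-1]
            elif kind == 2:
                traj = rng.uniform(0.1, 2.0, n)
            else:
                traj = np.full(n, rng.uniform(0.1, 2.0))
            ref = float(rng.uniform(0.05, 5.0))
            sub = bool(rng.integers(0, 2))
            par = bool(rng.integers(0, 2))
            assert priority_score(traj, ref, sub, par) == brute_force_score(
                traj, ref, sub, par
            )

    def test_relabeling_invariance(self):
        """Scores depend only on trajectories, never on protein identity."""
        rng = np.random.default_rng(5)
        trajs = [np.sort(rng.uniform(0.1, 2, 5)) for _ in range(10)]
        a = [priority_score(t, 1.0, False, False) for t in trajs]
        b = [priority_score(t, 1.0, False, False) for t in reversed(trajs)]
        assert a == b[::-1]


class TestFseofScan:
    def test_uncoupled_protein_scores_zero(self, toy_model):
        """A protein with no link to secretion or the cassette stays flat."""
        from pcsec import generate_recombinant_spec

        res = fseof_scan(toy_model, generate_recombinant_spec("plain", 300))
        s = res.scores.set_index("id")
        assert s.loc["hem2"].score == 0  # heme pathway unused by this cassette

    def test_own_machineries_positive(self, toy_model):
        from pcsec import amylase_like

        res = fseof_scan(toy_model, amylase_like("amy_t"))
        s = res.scores.set_index("id")
        for pid in ("ost", "pdi1", "sorter"):
            assert s.loc[pid].score >= 1

    def test_machinery_self_glycosylation_coupling(self, toy_model):
        """A DSB-only cassette raises the N-glycosylation load through the
        DSB machinery's own glycan sites relative to a bare cassette."""
        from pcsec import generate_recombinant_spec

        dsb = fseof_scan(toy_model, generate_recombinant_spec("dsbc", 480, n_DSB=4))
        bare = fseof_scan(toy_model, generate_recombinant_spec("bare", 480))
        t_dsb = dsb.trajectories["ost"]
        t_bare = bare.trajectories["ost"]
        assert (t_dsb[-1] - t_dsb[0]) > (t_bare[-1] - t_bare[0])

    def test_select_targets_deterministic_and_sorted(self, toy_model):
        from pcsec import amylase_like

        r1 = fseof_scan(toy_model, amylase_like("amy_d"))
        r2 = fseof_scan(toy_model, amylase_like("amy_d"))
        t1, t2 = select_targets(r1), select_targets(r2)
        assert t1.equals(t2)
        assert (t1.score.values == np.sort(t1.score.values)[::-1]).all()

    def test_min_score_five_empty(self, toy_model):
        from pcsec import amylase_like

        res = fseof_scan(toy_model, amylase_like("amy_e"))
        assert len(select_targets(res, min_score=5)) == 0

    def test_window_validation(self, toy_model):
        from pcsec import amylase_like

        with pytest.raises(ValueError):
            fseof_scan(toy_model, amylase_like("amy_w"), n_steps=2)
        with pytest.raises(ValueError):
            fseof_scan(toy_model, amylase_like("amy_w2"), mu_lo=0.2, mu_hi=0.1)


class TestFeatureImportancePlumbing:
    def test_small_grid_rejected(self, toy_model):
        from pcsec.targeting import feature_importance

        with pytest.raises(ValueError, match="underdetermined"):
            feature_importance(make_cassette_grid(10, 0), toy_model, seed=0)

    def test_grid_deterministic(self):
        g1 = make_cassette_grid(5, 42)
        g2 = make_cassette_grid(5, 42)
        assert [s.model_dump() for s in g1] == [s.model_dump() for s in g2]
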