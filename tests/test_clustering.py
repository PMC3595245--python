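"""Group affected rates, evaluation sampling, Ward clustering, regularity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from jointgroups.model import (
    AssessmentTable,
    JointGroup,
    flag_column,
    group_members,
)
from jointgroups.clustering import (
    GROUP_ORDER,
    characterize,
    group_rate_table,
    group_rates,
    regularity,
    sample_evaluations,
    ward_cluster,
)
from jointgroups.synthetic import CohortConfig, generate_cohort

from conftest import make_random_frame, make_zero_row


def ward_linkage_oracle(X: np.ndarray):
    """Independent Lance-Williams implementation of Ward agglomeration.

    Maintains squared inter-cluster distances and applies the Ward update
    d2(ij,k) = ((ni+nk) d2(i,k) + (nj+nk) d2(j,k) - nk d2(i,j)) / (ni+nj+nk).
    Returns the sorted merge heights (sqrt of merge d2, matching the
    Euclidean scale) and the flat partition at k clusters.
    """
    n = len(X)
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1).astype(float)
    np.fill_diagonal(d2, np.inf)
    sizes = {i: 1 for i in range(n)}
    members = {i: {i} for i in range(n)}
    active = list(range(n))
    heights = []
    partitions = {}
    while len(active) > 1:
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                d = d2[i, j]
                if best is None or d < best[0] - 1e-15:
                    best = (d, i, j)
        d, i, j = best
        heights.append(np.sqrt(d))
        ni, nj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            new = ((ni + nk) * d2[i, k] + (nj + nk) * d2[j, k] - nk * d) / (
                ni + nj + nk
            )
            d2[i, k] = d2[k, i] = new
        sizes[i] = ni + nj
        members[i] |= members[j]
        active.remove(j)
        partitions[len(active)] = [frozenset(members[c]) for c in active]
    return np.array(heights), partitions


class TestGroupRates:
    def test_four_tender_mcps_give_rate_point_four(self):
        flags = {flag_column(j, "tender"): 1 for j in group_members(JointGroup.MCP)[:4]}
        vec = group_rates(make_zero_row(**flags))
        assert vec.rates[JointGroup.MCP] == pytest.approx(0.4)
        assert vec.rates[JointGroup.PIP] == 0.0
        assert vec.rates[JointGroup.LARGE_WRIST] == 0.0

    def test_all_pip_tender_and_swollen_gives_two(self):
        flags = {}
        for j in group_members(JointGroup.PIP):
            flags[flag_column(j, "tender")] = 1
            flags[flag_column(j, "swollen")] = 1
        vec = group_rates(make_zero_row(**flags))
        assert vec.rates[JointGroup.PIP] == pytest.approx(2.0)

    def test_no_symptoms_gives_zero_vector(self):
        vec = group_rates(make_zero_row())
        assert all(v == 0.0 for v in vec.rates.values())

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_bounds_and_additive_decomposition(self, seed):
        rng = np.random.default_rng(seed)
        row = make_zero_row()
        for col in [c for c in row if c.endswith(("tender", "swollen"))]:
            row[col] = int(rng.integers(2))
        full = group_rates(row)
        tender_only = dict(row)
        swollen_only = dict(row)
        for col in list(row):
            if col.endswith("_swollen"):
                tender_only[col] = 0
            if col.endswith("_tender"):
                swollen_only[col] = 0
        t = group_rates(tender_only)
        s = group_rates(swollen_only)
        for g in JointGroup:
            assert 0.0 <= full.rates[g] <= 2.0
            assert full.rates[g] == pytest.approx(t.rates[g] + s.rates[g])

    def test_table_version_matches_row_version(self, small_table):
        table_rates = group_rate_table(small_table)
        for i in range(min(5, len(small_table))):
            row_vec = group_rates(small_table.df.iloc[i])
            for g in GROUP_ORDER:
                assert table_rates.loc[i, g.value] == pytest.approx(row_vec.rates[g])


class TestSampleEvaluations:
    def test_small_patients_fully_retained(self, small_table):
        out = sample_evaluations(small_table, max_per_patient=6, seed=0)
        before = small_table.df.groupby("patient_id").size()
        after = out.df.groupby("patient_id").size()
        for pid, n in before.items():
            assert after.get(pid, 0) == min(n, 6)

    def test_cap_enforced(self):
        rows = [make_zero_row(visit_index=v) for v in range(10)]
        table = AssessmentTable(pd.DataFrame(rows))
        out = sample_evaluations(table, max_per_patient=6, seed=1)
        assert len(out) == 6

    def test_target_n_exact_or_error(self, small_table):
        out = sample_evaluations(small_table, 6, target_n=20, seed=2)
        assert len(out) == 20
        with pytest.raises(ValueError, match="target_n"):
            sample_evaluations(small_table, 1, target_n=10_000, seed=2)

    def test_retention_uniform(self):
        """A 7-visit patient's visits are each kept 6/7 of the time."""
        rows = [make_zero_row(visit_index=v) for v in range(7)]
        table = AssessmentTable(pd.DataFrame(rows))
        n_rep = 20_000
        kept = np.zeros(7)
        for seed in range(n_rep):
            out = sample_evaluations(table, max_per_patient=6, seed=seed)
            kept[out.df["visit_index"].to_numpy()] += 1
        assert np.allclose(kept / n_rep, 6 / 7, atol=0.01)


class TestWardCluster:
    def make_features(self, X):
        df = pd.DataFrame(X, columns=[g.value for g in GROUP_ORDER])
        df.insert(0, "visit_index", 0)
        df.insert(0, "patient_id", [f"P{i}" for i in range(len(X))])
        return df

    def test_k_one_single_cluster(self, rng):
        X = rng.random((10, 3))
        model = ward_cluster(self.make_features(X), k=1)
        assert set(model.labels) == {1}

    def test_fewer_points_than_k_rejected(self, rng):
        X = rng.random((3, 3))
        with pytest.raises(ValueError, match="at least k"):
            ward_cluster(self.make_features(X), k=6)

    def test_two_planted_blobs_recovered(self, rng):
        a = rng.normal(0.1, 0.01, (25, 3))
        b = rng.normal(1.5, 0.01, (25, 3))
        X = np.vstack([a, b])
        model = ward_cluster(self.make_features(X), k=2)
        assert set(model.labels[:25]) == {1}
        assert set(model.labels[25:]) == {2}

    def test_labels_ordered_by_mean_total_rate(self, rng):
        X = np.vstack(
            [rng.normal(m, 0.02, (15, 3)) for m in (1.2, 0.1, 0.6)]
        )
        model = ward_cluster(self.make_features(X), k=3)
        totals = model.cluster_means.sum(axis=1)
        assert totals.is_monotonic_increasing

    def test_agrees_with_lance_williams_oracle(self, rng):
        """Merge heights and k=3 partitions match on random <=8-point sets."""
        from scipy.cluster.hierarchy import fcluster

        for _ in range(1000):
            n = int(rng.integers(4, 9))
            X = rng.random((n, 3)) * 2
            feats = self.make_features(X)
            model = ward_cluster(feats, k=1)
            heights, partitions = ward_linkage_oracle(X)
            assert np.allclose(np.sort(model.linkage_matrix[:, 2]), np.sort(heights))
            k = 3 if n > 3 else 2
            flat = fcluster(model.linkage_matrix, t=k, criterion="maxclust")
            got = {
                frozenset(np.flatnonzero(flat == c)) for c in np.unique(flat)
            }
            want = set(partitions[k])
            assert got == want


class TestCharacterize:
    def test_single_cluster_share_one_grand_mean(self, rng):
        X = rng.random((12, 3))
        feats = pd.DataFrame(X, columns=[g.value for g in GROUP_ORDER])
        feats.insert(0, "visit_index", 0)
        feats.insert(0, "patient_id", [f"P{i}" for i in range(12)])
        table = characterize(ward_cluster(feats, k=1))
        assert table.loc[1, "share"] == pytest.approx(1.0)
        assert np.allclose(
            table.loc[1, [g.value for g in GROUP_ORDER]].to_numpy(dtype=float),
            X.mean(axis=0),
        )

    def test_shares_sum_to_one(self, small_table):
        feats = group_rate_table(small_table)
        model = ward_cluster(feats, k=4)
        assert characterize(model)["share"].sum() == pytest.approx(1.0, abs=1e-12)


class TestRegularity:
    def model_with_labels(self, pid_labels):
        rows = []
        labels = []
        for pid, labs in pid_labels.items():
            for v, lab in enumerate(labs):
                rows.append({"patient_id": pid, "visit_index": v,
                             "large_wrist": 0.0, "mcp": 0.0, "pip": 0.0})
                labels.append(lab)
        from jointgroups.clustering import SubgroupModel

        feats = pd.DataFrame(rows)
        return SubgroupModel(
            k=max(labels),
            linkage_matrix=np.empty((0, 4)),
            features=feats,
            labels=np.array(labels),
            cluster_means=pd.DataFrame(),
            cluster_shares=pd.Series(dtype=float),
        )

    def test_three_of_four_is_regular(self):
        rep = regularity(self.model_with_labels({"A": [1, 1, 1, 2]}))
        assert rep.per_patient.loc[0, "regular"]

    def test_three_of_five_is_not_regular_strict(self):
        rep = regularity(self.model_with_labels({"A": [1, 1, 1, 2, 3]}))
        assert not rep.per_patient.loc[0, "regular"]
        assert rep.per_patient.loc[0, "modal_fraction"] == pytest.approx(0.6)

    def test_five_identical_is_regular(self):
        rep = regularity(self.model_with_labels({"A": [2] * 5}))
        assert rep.per_patient.loc[0, "regular"]

    def test_eligibility_requires_four_or_five(self):
        rep = regularity(
            self.model_with_labels({"A": [1, 1], "B": [1] * 6, "C": [1] * 4})
        )
        assert rep.n_eligible == 1
        assert rep.n_regular == 1


class TestArchetypeRecovery:
    def test_clusters_recover_planted_archetypes(self):
        from sklearn.metrics import adjusted_rand_score

        cfg = CohortConfig(
            n_patients=500,
            visits_per_patient=(3, 5),
            archetype_weights=(1,) * 6,
            archetype_activity=(
                (0.02, 0.02, 0.02),
                (0.80, 0.05, 0.05),
                (0.05, 0.80, 0.05),
                (0.05, 0.05, 0.80),
                (0.80, 0.80, 0.80),
                (0.80, 0.80, 0.05),
            ),
            joint_prevalence_multiplier={},
            right_bias=0.0,
            shoulder_swell_attenuation=1.0,
            within_block_rho=0.3,
            between_block_rho=0.05,
            visit_stability=1.0,
            seed=47,
        )
        table, truth = generate_cohort(cfg)
        feats = group_rate_table(sample_evaluations(table, 6, seed=0))
        model = ward_cluster(feats, k=6)
        planted = truth.archetype.loc[model.features["patient_id"]].to_numpy()
        assert adjusted_rand_score(planted, model.labels) >= 0.8
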