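"""Relative series, community heatmaps, peak calling, temporal ordering."""

import numpy as np
import pandas as pd
import pytest

from dnet import (
    CommunityHeatmap,
    heatmap_matrix,
    peak_time,
    relative_series,
    temporal_ordering,
)


def _expr(rows: dict) -> pd.DataFrame:
    n = len(next(iter(rows.values())))
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"t{j}" for j in range(n)]
    )


class TestRelativeSeries:
    def test_simple_arithmetic(self):
        assert relative_series(np.array([2.0, 4.0, 2.0])) == pytest.approx([0, 1, 0])

    def test_constant_series_gives_zero_vector(self):
        assert relative_series(np.array([5.0] * 6)) == pytest.approx([0.0] * 6)

    def test_norm_contract_on_random_series(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            out = relative_series(rng.gamma(2, 5, size=12))
            assert out[0] == 0.0
            assert np.linalg.norm(out) == pytest.approx(1.0) or np.all(out == 0)


class TestHeatmapMatrix:
    def test_identical_conditions_cancel_to_zero_row(self):
        t = _expr({"g": [1, 3, 5, 2]})
        hm = heatmap_matrix(["g"], t, t.copy())
        assert hm.values.loc["g"].to_numpy() == pytest.approx([0, 0, 0, 0])
        assert hm.peak_time is None

    def test_single_gene_direct_arithmetic(self):
        t = _expr({"g": [1, 1, 3]})
        u = _expr({"g": [1, 1, 1]})
        hm = heatmap_matrix(["g"], t, u)
        assert hm.values.loc["g"].to_numpy() == pytest.approx([0, 0, 1])
        assert (hm.peak_time, hm.peak_sign, hm.peak_magnitude) == (2, "up", 1.0)

    def test_rows_unit_norm_and_column0_zero(self):
        rng = np.random.default_rng(7)
        t = _expr({f"g{i}": rng.gamma(2, 5, 10) for i in range(8)})
        u = _expr({f"g{i}": rng.gamma(2, 5, 10) for i in range(8)})
        hm = heatmap_matrix(list(t.index), t, u)
        vals = hm.values.to_numpy()
        assert np.allclose(vals[:, 0], 0.0)
        norms = np.linalg.norm(vals, axis=1)
        assert np.all((np.isclose(norms, 1.0)) | (np.isclose(norms, 0.0)))
        assert np.all((vals >= -1 - 1e-12) & (vals <= 1 + 1e-12))

    def test_antisymmetric_under_condition_swap(self):
        rng = np.random.default_rng(8)
        t = _expr({f"g{i}": rng.gamma(2, 5, 8) for i in range(5)})
        u = _expr({f"g{i}": rng.gamma(2, 5, 8) for i in range(5)})
        fwd = heatmap_matrix(list(t.index), t, u).values.sort_index()
        rev = heatmap_matrix(list(t.index), u, t).values.sort_index()
        assert np.allclose(fwd.to_numpy(), -rev.to_numpy())

    def test_missing_gene_raises_with_name(self):
        t = _expr({"g": [1, 2, 3]})
        with pytest.raises(KeyError, match="absent"):
            heatmap_matrix(["absent"], t, t)

    def test_row_order_consistent_with_naive_complete_linkage(self):
        """scipy leaf order must be a valid flattening of the farthest-point
        merge tree computed independently by naive agglomeration."""
        rng = np.random.default_rng(9)
        t = _expr({f"g{i}": rng.gamma(2, 5, 10) for i in range(9)})
        u = _expr({f"g{i}": rng.gamma(2, 5, 10) for i in range(9)})
        hm = heatmap_matrix(list(t.index), t, u)

        # recompute the rows in input order (before reordering)
        from dnet.temporal import _unit_rows, relative_series

        genes = list(t.index)
        rows = _unit_rows(
            np.vstack([relative_series(t.loc[g].to_numpy()) for g in genes])
            - np.vstack([relative_series(u.loc[g].to_numpy()) for g in genes])
        )
        # naive complete-linkage agglomeration: repeatedly merge the two
        # clusters whose *maximum* pairwise row distance is smallest
        clusters = [{i} for i in range(len(genes))]
        merged_sets = []
        while len(clusters) > 1:
            best = None
            for i in range(len(clusters)):
                for j in range(i + 1, len(clusters)):
                    d = max(
                        np.linalg.norm(rows[a] - rows[b])
                        for a in clusters[i]
                        for b in clusters[j]
                    )
                    if best is None or d < best[0]:
                        best = (d, i, j)
            _, i, j = best
            new = clusters[i] | clusters[j]
            merged_sets.append(new)
            clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [new]
        order = [genes.index(g) for g in hm.values.index]
        pos = {leaf: p for p, leaf in enumerate(order)}
        for cluster in merged_sets:
            positions = sorted(pos[leaf] for leaf in cluster)
            assert positions == list(range(positions[0], positions[0] + len(cluster)))


class TestPeakTime:
    def test_cancelling_rows_flag_no_response(self):
        hm = CommunityHeatmap(
            community_label="C0",
            values=pd.DataFrame([[0, 1, 0], [0, -1, 0]], index=["a", "b"],
                                columns=["t0", "t1", "t2"]),
        )
        assert peak_time(hm) is None

    def test_down_regulation_sign(self):
        hm = CommunityHeatmap(
            community_label="C0",
            values=pd.DataFrame([[0, -0.2, -0.9]], index=["a"],
                                columns=["t0", "t1", "t2"]),
        )
        assert peak_time(hm) == (2, "down", pytest.approx(0.9))

    def test_t0_excluded_even_for_nonzero_column(self):
        hm = CommunityHeatmap(
            community_label="C0",
            values=pd.DataFrame([[5.0, 0.1, 0.0]], index=["a"],
                                columns=["t0", "t1", "t2"]),
        )
        assert peak_time(hm)[0] == 1

    def test_median_aggregate_option(self):
        values = pd.DataFrame(
            [[0, 0.9, 0.1], [0, 0.1, 0.2], [0, 0.1, 0.3]],
            index=list("abc"), columns=["t0", "t1", "t2"],
        )
        hm = CommunityHeatmap(community_label="C0", values=values)
        assert peak_time(hm, aggregate="mean")[0] == 1
        assert peak_time(hm, aggregate="median")[0] == 2


class TestTemporalOrdering:
    @staticmethod
    def _hm(label, peak, n_tp=6, sign="up", mag=0.5):
        row = np.zeros(n_tp)
        row[peak] = mag if sign == "up" else -mag
        values = pd.DataFrame([row], index=["g"],
                              columns=[f"t{j}" for j in range(n_tp)])
        return CommunityHeatmap(label, values, peak, sign, mag)

    def test_sorted_by_peak_time(self):
        ordering = temporal_ordering([self._hm("C1", 4), self._hm("C0", 2)])
        assert [e[0] for e in ordering.entries] == ["C0", "C1"]

    def test_single_community_silent_timepoints(self):
        ordering = temporal_ordering([self._hm("C0", 3, n_tp=6)])
        assert ordering.entries[0][:2] == ("C0", 3)
        assert ordering.silent_timepoints == {0, 1, 2, 4, 5}

    def test_peak_tie_falls_back_to_label(self):
        ordering = temporal_ordering([self._hm("C1", 2), self._hm("C0", 2)])
        assert [e[0] for e in ordering.entries] == ["C0", "C1"]

    def test_no_response_heatmaps_excluded(self):
        silent = CommunityHeatmap(
            "C9", pd.DataFrame([[0.0, 0.0, 0.0]], index=["g"],
                               columns=["t0", "t1", "t2"]),
        )
        ordering = temporal_ordering([silent, self._hm("C0", 1, n_tp=3)])
        assert [e[0] for e in ordering.entries] == ["C0"]
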