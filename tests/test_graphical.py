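import random
from itertools import chain, combinations

import numpy as np
import pytest

from closedmcpmod import (
    CandidateModel,
    CandidateSet,
    DoseDesign,
    GraphMTP,
    closed_graphical_mcpmod,
    local_levels,
    scaled_mean_profile,
    summarize,
)
from closedmcpmod.inference import critical_value
from closedmcpmod.simulate import Scenario, simulate_trial

from _oracles import oracle_group_pvalue

ALPHA = 0.025

# Published local levels (fractions of alpha) for the default
# three-dose primary/secondary graph, by intersection.
LEVEL_ROWS = [
    (("H11", "H12", "H13", "H21", "H22", "H23"),
     {"H11": 1 / 3, "H12": 1 / 3, "H13": 1 / 3, "H21": 0, "H22": 0,
      "H23": 0}),
    (("H21", "H22", "H23"),
     {"H21": 1 / 3, "H22": 1 / 3, "H23": 1 / 3}),
    (("H11", "H12", "H21", "H22", "H23"),
     {"H11": 1 / 3, "H12": 1 / 3, "H21": 0, "H22": 0, "H23": 1 / 3}),
    (("H11", "H12", "H21", "H22"),
     {"H11": 1 / 2, "H12": 1 / 2, "H21": 0, "H22": 0}),
    (("H11", "H21", "H22", "H23"),
     {"H11": 1 / 3, "H21": 0, "H22": 1 / 3, "H23": 1 / 3}),
    (("H11", "H21", "H23"),
     {"H11": 1 / 2, "H21": 0, "H23": 1 / 2}),
    (("H11", "H23"), {"H11": 1 / 2, "H23": 1 / 2}),
]


def _independent_local_levels(graph, intersection, order):
    """Dict-based re-implementation of the node-removal algebra."""
    labels = list(graph.labels)
    lv = {h: graph.levels[i] for i, h in enumerate(labels)}
    g = {
        (a, b): graph.transitions[i, j]
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
        if i != j
    }
    alive = list(labels)
    for j in order:
        rest = [h for h in alive if h != j]
        for l in rest:
            lv[l] = lv[l] + lv[j] * g[(j, l)]
        newg = {}
        for l in rest:
            for m in rest:
                if l == m:
                    continue
                den = 1.0 - g[(l, j)] * g[(j, l)]
                newg[(l, m)] = (
                    (g[(l, m)] + g[(l, j)] * g[(j, m)]) / den
                    if den > 1e-12 else 0.0
                )
        g = newg
        alive = rest
    return {h: lv[h] for h in intersection}


class TestLocalLevels:
    @pytest.mark.parametrize("intersection,expected", LEVEL_ROWS)
    def test_published_rows(self, intersection, expected):
        graph = GraphMTP.two_endpoint_default(3)
        lv = local_levels(graph, intersection, alpha=ALPHA)
        for h, frac in expected.items():
            assert lv[h] == pytest.approx(frac * ALPHA, abs=1e-12), h

    def test_all_63_intersections_sum_at_most_alpha(self):
        graph = GraphMTP.two_endpoint_default(3)
        labels = list(graph.labels)
        for I in chain.from_iterable(
            combinations(labels, r) for r in range(1, 7)
        ):
            lv = local_levels(graph, I, alpha=ALPHA)
            assert sum(lv.values()) <= ALPHA + 1e-12
            if all(h in I for h in ("H11", "H12", "H13")):
                # no secondary gets a positive level; primaries carry alpha
                assert all(lv[h] == 0.0 for h in I if h.startswith("H2"))
                assert sum(lv.values()) == pytest.approx(ALPHA)

    def test_removal_order_invariance(self):
        graph = GraphMTP.two_endpoint_default(3)
        labels = list(graph.labels)
        rng = random.Random(0)
        for I in [("H11", "H23"), ("H12", "H21", "H22"),
                  ("H11", "H12", "H22", "H23")]:
            ref = local_levels(graph, I, alpha=ALPHA)
            outside = [h for h in labels if h not in I]
            for _ in range(6):
                order = outside[:]
                rng.shuffle(order)
                alt = _independent_local_levels(graph, I, order)
                for h in I:
                    assert ref[h] == pytest.approx(alt[h] * ALPHA, abs=1e-12)

    def test_generalized_edge_weight_conserves_level(self):
        for x in (0.0, 0.3, 1.0):
            graph = GraphMTP.two_endpoint_default(3, x=x)
            np.testing.assert_allclose(graph.transitions.sum(axis=1), 1.0)
            lv = local_levels(graph, graph.labels, alpha=ALPHA)
            assert sum(lv.values()) == pytest.approx(ALPHA)
            # symmetric across the three doses
            assert lv["H11"] == pytest.approx(lv["H12"]) == pytest.approx(
                lv["H13"]
            )

    def test_unknown_labels_rejected(self):
        graph = GraphMTP.two_endpoint_default(2)
        with pytest.raises(ValueError, match="not in graph"):
            local_levels(graph, ("H19",))

    def test_graph_validation(self):
        with pytest.raises(ValueError):
            GraphMTP(("a", "b"), [0.6, 0.6], np.zeros((2, 2)))
        with pytest.raises(ValueError):
            GraphMTP(("a", "b"), [0.5, 0.5], np.array([[0.5, 0.5],
                                                       [0.0, 0.0]]))


def _two_endpoint_data(design, effects, seed):
    truth = CandidateModel("emax", {"ed50": 0.2}, label="truth")
    out = []
    for e_idx, eff in enumerate(effects):
        sc = Scenario(design=design, model=truth, effect=eff, nsim=1,
                      seed=seed, scenario_id=e_idx)
        out.append(simulate_trial(sc, 0))
    return out


@pytest.fixture(scope="module")
def k2_design():
    return DoseDesign((0.0, 0.5, 1.0), (60, 60, 60))


@pytest.fixture(scope="module")
def k2_cset():
    return CandidateSet([
        CandidateModel("emax", {"ed50": 0.1}, label="steep"),
        CandidateModel("emax", {"ed50": 0.6}, label="shallow"),
    ])


class TestGraphicalClosure:
    def test_k1_is_hierarchical_testing(self):
        design = DoseDesign((0.0, 1.0), (80, 80))
        cs = CandidateSet([CandidateModel("emax", {"ed50": 0.2})])
        strong = _two_endpoint_data(design, (1.0, 1.0), seed=3)
        res = closed_graphical_mcpmod(strong, design, cs, alpha=ALPHA,
                                      seed=1)
        assert res.rejected["H11"] and res.rejected["H21"]
        # strong secondary but null primary: nothing may be rejected
        mixed = _two_endpoint_data(design, (0.0, 1.0), seed=4)
        res = closed_graphical_mcpmod(mixed, design, cs, alpha=ALPHA, seed=1)
        assert not res.rejected["H21"]
        assert not res.rejected["H11"]

    def test_successiveness_emerges_from_graph(self, k2_design, k2_cset):
        """A secondary hypothesis is never rejected unless the primary
        at the same dose is."""
        for seed in range(4):
            data = _two_endpoint_data(k2_design, (0.45, 0.45), seed=seed)
            res = closed_graphical_mcpmod(data, k2_design, k2_cset,
                                          alpha=ALPHA, seed=seed)
            for i in (1, 2):
                if res.rejected[f"H2{i}"]:
                    assert res.rejected[f"H1{i}"]

    def test_zero_level_group_never_significant(self, k2_design, k2_cset):
        from closedmcpmod.graphical import test_intersection_graphical

        data = _two_endpoint_data(k2_design, (3.0, 3.0), seed=9)
        stats = [summarize(d, k2_design) for d in data]
        # secondaries carry level 0 here: even overwhelming secondary
        # data cannot reject
        reject, p = test_intersection_graphical(
            ("H21", "H22"), {"H21": 0.0, "H22": 0.0}, stats, k2_design,
            k2_cset, alpha=ALPHA,
        )
        assert not reject and p == 1.0

    def test_matches_brute_force_closure(self, k2_design, k2_cset):
        """Report equals an independent exhaustive-closure oracle."""
        data = _two_endpoint_data(k2_design, (0.5, 0.4), seed=12)
        res = closed_graphical_mcpmod(data, k2_design, k2_cset,
                                      alpha=ALPHA, seed=2)
        graph = GraphMTP.two_endpoint_default(2)
        stats = [summarize(d, k2_design) for d in data]
        profiles = {
            m.label: np.asarray(scaled_mean_profile(m, k2_design, 1.0))
            for m in k2_cset
        }
        labels = list(graph.labels)
        inter_reject = {}
        for I in chain.from_iterable(
            combinations(labels, r) for r in range(1, 5)
        ):
            lv = local_levels(graph, I, alpha=ALPHA)
            rej = False
            for endpoint in (1, 2):
                doses = sorted(int(h[2:]) for h in I
                               if h.startswith(f"H{endpoint}"))
                if not doses:
                    continue
                w = sum(lv[f"H{endpoint}{i}"] for i in doses)
                if w <= 0:
                    continue
                st = stats[endpoint - 1]
                p = oracle_group_pvalue(
                    st.means, st.s, k2_design.n, st.df, profiles, doses
                )
                rej = rej or (p < w)
            inter_reject[frozenset(I)] = rej
        for h in labels:
            expected = all(r for I, r in inter_reject.items() if h in I)
            assert res.rejected[h] == expected, h

    def test_two_endpoint_null_fwer_controlled(self, k2_design, k2_cset):
        """Simulated familywise error over both endpoints stays below
        alpha (vectorized with per-subset critical values)."""
        from closedmcpmod.closed import _intersection_contrasts
        from closedmcpmod.contrasts import correlation_matrix

        graph = GraphMTP.two_endpoint_default(2)
        labels = list(graph.labels)
        df = k2_design.N - 3
        # unique (subset, level-fraction) critical values
        crit = {}
        group_info = {}
        for I in chain.from_iterable(
            combinations(labels, r) for r in range(1, 5)
        ):
            lv = local_levels(graph, I, alpha=ALPHA)
            groups = []
            for endpoint in (1, 2):
                doses = tuple(sorted(
                    int(h[2:]) for h in I if h.startswith(f"H{endpoint}")
                ))
                if not doses:
                    continue
                w = sum(lv[f"H{endpoint}{i}"] for i in doses)
                if w <= 0:
                    continue
                key = (doses, round(w / ALPHA, 12))
                if key not in crit:
                    cs, _ = _intersection_contrasts(
                        doses, k2_design, k2_cset, True
                    )
                    R = correlation_matrix(cs, k2_design)
                    C = np.array([np.asarray(c) for c in cs])
                    crit[key] = (
                        C,
                        np.sqrt((C**2 / k2_design.n).sum(axis=1)),
                        critical_value(R, df, alpha=w, seed=0),
                    )
                groups.append((endpoint, key))
            group_info[frozenset(I)] = groups

        nsim = 2000
        rng = np.random.default_rng(77)
        n = k2_design.n
        rej_any = np.zeros(nsim, dtype=bool)
        # independent endpoints under the complete null
        means = rng.standard_normal((nsim, 2, 3)) / np.sqrt(n)
        s = np.sqrt(rng.chisquare(df, (nsim, 2)) / df)
        tmax = {}
        for key, (C, scale, c) in crit.items():
            for endpoint in (1, 2):
                T = (means[:, endpoint - 1] @ C.T) / (
                    s[:, endpoint - 1][:, None] * scale
                )
                tmax[(endpoint, key)] = T.max(axis=1) >= c
        inter_rej = {
            I: np.any(
                [tmax[(e, key)] for e, key in groups], axis=0
            ) if groups else np.zeros(nsim, dtype=bool)
            for I, groups in group_info.items()
        }
        # a familywise error occurs as soon as any intersection of the
        # (all-true) family is rejected along a full closure chain; the
        # full intersection is the gatekeeper
        full = frozenset(labels)
        fwer = inter_rej[full].mean()
        se = np.sqrt(ALPHA * (1 - ALPHA) / nsim)
        assert fwer <= ALPHA + 3 * se
        # and no elementary hypothesis is rejected more often than that
        for h in labels:
            elem = np.all(
                [r for I, r in inter_rej.items() if h in I], axis=0
            )
            assert elem.mean() <= ALPHA + 3 * se
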