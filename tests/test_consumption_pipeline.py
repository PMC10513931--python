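"""Footprint pipeline: Leontief runs, origin decomposition, COICOP, food footprint."""

import numpy as np
import pandas as pd
import pytest

from conftest import neumann_footprint
from footprintflow import consumption_pipeline as cp
from footprintflow.extension_builder import ExtensionTable
from footprintflow.mrio_model import MRIOWorld, technical_coefficients
from footprintflow.synthetic_data import WorldSpec, generate_world


def _autarkic_world(f=0.5, a=0.2, d=100.0):
    x = d / (1 - a)
    world = MRIOWorld(["A"], ["s1"], [[a * x]], [x], [[d]], [100.0])
    E = np.zeros((6, 1))
    E[0, 0] = f * x
    ext = ExtensionTable(E=E, F=E / x)
    return world, ext


def test_run_efmrio_scalar_closed_form():
    world, ext = _autarkic_world()
    flows = cp.run_efmrio(world, ext, "A")
    assert flows.total == pytest.approx(0.5 * 100.0 / 0.8)  # f d / (1-a)


def test_run_efmrio_zero_demand_gives_zero_flows():
    world, ext = _autarkic_world()
    world.D[:] = 0.0
    world.Z[:] = 0.0
    world.x[:] = 0.0
    flows = cp.run_efmrio(world, ExtensionTable(E=ext.E * 0, F=ext.F * 0), "A")
    assert flows.total == 0.0


def test_run_efmrio_matches_series_oracle_per_land_type(small_world):
    w = small_world.world
    A = technical_coefficients(w).A
    for consumer in w.regions:
        flows = cp.run_efmrio(w, small_world.extension, consumer)
        d = w.D[:, w.regions.index(consumer)]
        oracle = neumann_footprint(small_world.extension.F, A, d)
        assert np.allclose(flows.by_land_type().to_numpy(), oracle, rtol=1e-10)


def test_footprint_tensor_marginals_agree(small_world):
    """Producer and demand attributions are the two marginals of the tensor."""
    w = small_world.world
    T = cp.footprint_tensor(w, small_world.extension, "R02")
    flows = cp.run_efmrio(w, small_world.extension, "R02")
    demand = cp.demand_side_footprints(w, small_world.extension, "R02")
    n_land = T.shape[0]
    producer = T.sum(axis=2)
    assert np.allclose(
        producer.reshape(n_land, w.n_regions, w.n_sectors), flows.cells, rtol=1e-9
    )
    assert np.allclose(T.sum(axis=1), demand, rtol=1e-9)
    assert flows.total == pytest.approx(demand.sum(), rel=1e-9)


def test_decompose_origin_autarky_and_foreign():
    world, ext = _autarkic_world()
    flows = cp.run_efmrio(world, ext, "A")
    shares = cp.decompose_origin(flows, {"A"})
    assert (shares.domestic, shares.intra_group, shares.extra_group) == (1.0, 0.0, 0.0)

    # all production in a non-member region
    cells = np.zeros((6, 2, 1))
    cells[0, 1, 0] = 5.0
    foreign = cp.FootprintFlows("A", ["A", "B"], ["s1"], cells)
    shares = cp.decompose_origin(foreign, {"A"})
    assert shares.extra_group == pytest.approx(1.0)


def test_decompose_origin_partition_sum_oracle(small_world):
    w = small_world.world
    group = set(small_world.eu_members)
    for consumer in w.regions:
        flows = cp.run_efmrio(w, small_world.extension, consumer)
        shares = cp.decompose_origin(flows, group)
        by_region = flows.by_producing_region()
        dom = by_region[consumer]
        intra = sum(v for r, v in by_region.items() if r in group and r != consumer)
        extra = flows.total - dom - intra
        assert shares.domestic == pytest.approx(dom / flows.total, rel=1e-9)
        assert shares.intra_group == pytest.approx(intra / flows.total, rel=1e-9)
        assert shares.extra_group == pytest.approx(extra / flows.total, rel=1e-9)
        assert shares.domestic + shares.intra_group + shares.extra_group == pytest.approx(1.0)


def test_enlarging_group_never_decreases_internal_share(small_world):
    w = small_world.world
    flows = cp.run_efmrio(w, small_world.extension, "R01")
    inside = []
    for k in range(len(w.regions) + 1):
        shares = cp.decompose_origin(flows, set(w.regions[:k]))
        inside.append(shares.domestic + shares.intra_group)
    assert all(b >= a - 1e-12 for a, b in zip(inside, inside[1:]))


def test_decompose_origin_zero_total_raises():
    flows = cp.FootprintFlows("A", ["A"], ["s1"], np.zeros((6, 1, 1)))
    with pytest.raises(ValueError, match="undefined"):
        cp.decompose_origin(flows, {"A"})


def test_recategorize_identity_and_split():
    sectors = ["A:s1", "A:s2"]
    identity = cp.CoicopConcordance(
        shares=pd.DataFrame(np.eye(2), index=sectors, columns=["c1", "c2"])
    )
    fp = pd.Series([3.0, 4.0], index=sectors)
    out = cp.recategorize_coicop(fp, identity)
    assert np.allclose(out.to_numpy(), [3.0, 4.0])

    split = cp.CoicopConcordance(
        shares=pd.DataFrame([[0.3, 0.7], [1.0, 0.0]], index=sectors, columns=["c1", "c2"])
    )
    out = cp.recategorize_coicop(pd.Series([100.0, 0.0], index=sectors), split)
    assert out["c1"] == pytest.approx(30.0)
    assert out["c2"] == pytest.approx(70.0)


def test_recategorize_conserves_total(small_world):
    w = small_world.world
    demand = cp.demand_side_footprints(w, small_world.extension, "R03").sum(axis=0)
    out = cp.recategorize_coicop(demand, small_world.concordance)
    assert out.sum() == pytest.approx(demand.sum(), rel=1e-9)


def test_concordance_row_sum_violation_raises():
    with pytest.raises(ValueError, match="sum to 1"):
        cp.CoicopConcordance(
            shares=pd.DataFrame([[0.5, 0.4]], index=["A:s1"], columns=["c1", "c2"])
        )


def test_food_footprint_cases():
    cats = ["meat", "services"]
    conc = cp.CoicopConcordance(
        shares=pd.DataFrame([[0.5, 0.5]], index=["A:s1"], columns=cats),
        food_categories=frozenset(["meat"]),
    )
    fp = pd.Series([60.0, 40.0], index=cats)
    ff = cp.food_footprint(fp, conc, population=10.0)
    assert ff.ff_per_capita == pytest.approx(6.0)
    assert ff.total_ef_per_capita == pytest.approx(10.0)
    assert ff.ff_share == pytest.approx(0.6)

    none_food = cp.CoicopConcordance(shares=conc.shares, food_categories=frozenset())
    assert cp.food_footprint(fp, none_food, 10.0).ff_per_capita == 0.0

    all_food = cp.CoicopConcordance(
        shares=conc.shares, food_categories=frozenset(cats)
    )
    ff = cp.food_footprint(fp, all_food, 10.0)
    assert ff.ff_per_capita == pytest.approx(ff.total_ef_per_capita)

    with pytest.raises(ValueError, match="population"):
        cp.food_footprint(fp, conc, 0.0)


def test_ff_share_matches_reported_ratio():
    """A 1.06 gha food footprint out of 3.47 gha total is ~30%."""
    cats = ["food", "rest"]
    conc = cp.CoicopConcordance(
        shares=pd.DataFrame([[0.5, 0.5]], index=["A:s1"], columns=cats),
        food_categories=frozenset(["food"]),
    )
    fp = pd.Series([1.06, 3.47 - 1.06], index=cats)
    share = cp.food_footprint(fp, conc, 1.0).ff_share
    assert share == pytest.approx(0.3054755, abs=1e-6)


def test_planted_truth_recovery(planted):
    """Per-category footprints on the autarkic world match the closed form."""
    bundle = planted.bundle
    for region in bundle.world.regions:
        demand = cp.demand_side_footprints(bundle.world, bundle.extension, region).sum(
            axis=0
        )
        coicop = cp.recategorize_coicop(demand, bundle.concordance)
        expected = planted.expected_category_gha.loc[region]
        assert np.allclose(coicop.to_numpy(), expected.to_numpy(), rtol=1e-12)
        flows = cp.run_efmrio(bundle.world, bundle.extension, region)
        shares = cp.decompose_origin(flows, set(bundle.eu_members))
        assert shares.domestic == pytest.approx(1.0, abs=1e-12)


def test_planted_truth_single_edge_perturbation(planted):
    """Redirecting one demand edge across the border moves exactly its gha."""
    bundle = planted.bundle
    world = bundle.world
    D = world.D.copy()
    # region R02's demand for R01's first sector: a new cross-border edge
    moved = 50.0
    D[0, 0] -= moved
    D[0, 1] += moved
    perturbed = MRIOWorld(
        world.regions, world.sectors, world.Z, world.x, D, world.populations
    )
    flows = cp.run_efmrio(perturbed, bundle.extension, "R02")
    shares = cp.decompose_origin(flows, set(world.regions))  # everyone in group
    A = technical_coefficients(world).A
    a0 = A[0, 0]
    edge_gha = bundle.extension.F[:, 0].sum() * moved / (1 - a0)
    base_total = planted.expected_category_gha.loc["R02"].sum()
    assert flows.total == pytest.approx(base_total + edge_gha, rel=1e-10)
    assert shares.intra_group == pytest.approx(edge_gha / flows.total, rel=1e-9)


def test_unknown_consumer_raises(small_world):
    with pytest.raises(KeyError):
        cp.run_efmrio(small_world.world, small_world.extension, "NOPE")
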