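"""Allocation of production footprints to sectors and intensity normalization."""

import numpy as np
import pandas as pd
import pytest

from footprintflow.core_accounts import LAND_TYPES
from footprintflow.extension_builder import (
    AllocationError,
    SectorAllocationScheme,
    build_extension,
    intensity_form,
)
from footprintflow.mrio_model import MRIOWorld
from footprintflow.synthetic_data import WorldSpec, generate_world


def _one_region_world(x):
    x = np.asarray(x, float)
    S = len(x)
    Z = np.zeros((S, S))
    return MRIOWorld(["A"], [f"s{i + 1}" for i in range(S)], Z, x, x[:, None], [1.0])


def _scheme(S, **kw):
    uniform = np.full((1, S), 1.0 / S)
    defaults = dict(
        cropland_sectors=[0, 1],
        grazing_sectors=[2],
        forest_sector=3,
        fishing_sector=4,
        emission_share=uniform,
        value_added_share=uniform,
    )
    defaults.update(kw)
    return SectorAllocationScheme(**defaults)


def _efp(region="A", **gha):
    rows = [
        {"region": region, "land_type": lt, "gha": gha.get(lt, 0.0)} for lt in LAND_TYPES
    ]
    return pd.DataFrame(rows)


def test_cropland_split_by_explicit_weights():
    world = _one_region_world([100.0] * 5)
    scheme = _scheme(5, within_group_weights={"cropland": [0.5, 0.5]})
    ext = build_extension(_efp(cropland=80.0), scheme, world)
    crop = ext.E[list(LAND_TYPES).index("cropland")]
    assert crop[0] == pytest.approx(40.0)
    assert crop[1] == pytest.approx(40.0)


def test_carbon_split_by_emission_share():
    world = _one_region_world([100.0] * 5)
    shares = np.array([[0.25, 0.75, 0.0, 0.0, 0.0]])
    ext = build_extension(_efp(carbon=100.0), _scheme(5, emission_share=shares), world)
    carbon = ext.E[list(LAND_TYPES).index("carbon")]
    assert carbon[0] == pytest.approx(25.0)
    assert carbon[1] == pytest.approx(75.0)
    assert carbon[2:].sum() == 0.0


def test_builtup_split_by_value_added_and_singletons():
    world = _one_region_world([100.0] * 5)
    va = np.array([[0.1, 0.2, 0.3, 0.4, 0.0]])
    ext = build_extension(
        _efp(builtup=10.0, forest=7.0, fishing=3.0),
        _scheme(5, value_added_share=va),
        world,
    )
    built = ext.E[list(LAND_TYPES).index("builtup")]
    assert np.allclose(built, [1.0, 2.0, 3.0, 4.0, 0.0])
    assert ext.E[list(LAND_TYPES).index("forest")][3] == pytest.approx(7.0)
    assert ext.E[list(LAND_TYPES).index("fishing")][4] == pytest.approx(3.0)


def test_default_weights_are_output_shares():
    world = _one_region_world([300.0, 100.0, 50.0, 50.0, 50.0])
    ext = build_extension(_efp(cropland=80.0), _scheme(5), world)
    crop = ext.E[0]
    assert crop[0] == pytest.approx(60.0)  # 300/(300+100) of 80
    assert crop[1] == pytest.approx(20.0)


def test_allocation_conserves_efp_on_random_worlds():
    """Re-summing E over each region's sectors recovers the input EF_P."""
    for seed in range(5):
        sw = generate_world(WorldSpec(n_regions=3, n_sectors=6, seed=seed))
        S = sw.world.n_sectors
        for ri, region in enumerate(sw.world.regions):
            for li, lt in enumerate(LAND_TYPES):
                target = float(
                    sw.efp.query("region == @region and land_type == @lt")["gha"].iloc[0]
                )
                got = sw.extension.E[li, ri * S : (ri + 1) * S].sum()
                assert got == pytest.approx(target, rel=1e-9)


def test_group_permutation_equivariance():
    """Permuting group members with matching weights permutes E columns."""
    world = _one_region_world([100.0] * 5)
    a = build_extension(
        _efp(cropland=80.0),
        _scheme(5, cropland_sectors=[0, 1], within_group_weights={"cropland": [0.3, 0.7]}),
        world,
    )
    b = build_extension(
        _efp(cropland=80.0),
        _scheme(5, cropland_sectors=[1, 0], within_group_weights={"cropland": [0.7, 0.3]}),
        world,
    )
    assert np.allclose(a.E, b.E)


def test_missing_land_type_and_zero_weights_raise():
    world = _one_region_world([100.0] * 5)
    with pytest.raises(AllocationError, match="missing EF_P"):
        build_extension(_efp().iloc[:-1], _scheme(5), world)
    with pytest.raises(AllocationError, match="sum to 0"):
        build_extension(
            _efp(cropland=10.0),
            _scheme(5, within_group_weights={"cropland": [0.0, 0.0]}),
            world,
        )


def test_disjointness_enforced_unless_relaxed():
    uniform = np.full((1, 2), 0.5)
    with pytest.raises(ValueError, match="disjoint"):
        SectorAllocationScheme(
            cropland_sectors=[0],
            grazing_sectors=[0],
            forest_sector=1,
            fishing_sector=1,
            emission_share=uniform,
            value_added_share=uniform,
        )
    SectorAllocationScheme(
        cropland_sectors=[0],
        grazing_sectors=[0],
        forest_sector=1,
        fishing_sector=1,
        emission_share=uniform,
        value_added_share=uniform,
        strict=False,
    )


@pytest.mark.parametrize(
    "E, x, expected",
    [([[50.0]], [200.0], 0.25), ([[0.0]], [0.0], 0.0)],
)
def test_intensity_form_values(E, x, expected):
    assert intensity_form(np.array(E), np.array(x))[0, 0] == pytest.approx(expected)


def test_intensity_form_round_trip():
    """F @ diag(x) reconstructs E wherever output is positive."""
    rng = np.random.default_rng(9)
    E = rng.gamma(2.0, 10.0, (6, 8))
    x = rng.uniform(10, 100, 8)
    F = intensity_form(E, x)
    assert np.allclose(F * x[None, :], E, rtol=1e-12)


def test_stranded_footprint_warns():
    with pytest.warns(UserWarning, match="stranded"):
        F = intensity_form(np.array([[5.0, 1.0]]), np.array([0.0, 10.0]))
    assert F[0, 0] == 0.0
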