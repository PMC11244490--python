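"""Shared fixtures: small labelled stands rendered once per session."""

from __future__ import annotations

import numpy as np
import pytest

from bamboostand.cloud import PointCloud
from bamboostand.synthetic import ScannerConfig, StandConfig, generate_stand, render_als, render_tls


@pytest.fixture(scope="session")
def small_truth():
    return generate_stand(StandConfig(n_plants=6, min_spacing_m=2.0, seed=5))


@pytest.fixture(scope="session")
def small_als(small_truth):
    return render_als(small_truth, ScannerConfig.als(seed=6))


@pytest.fixture(scope="session")
def small_tls_projected(small_truth):
    """TLS rendering kept in the projected frame (identity scanner transform)."""
    cloud, _ = render_tls(small_truth, ScannerConfig.tls(seed=7))
    return cloud.with_xyz(cloud.xyz, frame="projected")


@pytest.fixture(scope="session")
def separated_truth():
    """Nine plants on a 12 m plot with spacing >= 2 x crown radius."""
    return generate_stand(
        StandConfig(
            plot_size_m=(12.0, 12.0),
            n_plants=9,
            min_spacing_m=3.0,
            crown_radius_m=0.9,
            max_lean_deg=1.0,
            seed=17,
        )
    )


def normalized_truth_cloud(truth, cloud) -> PointCloud:
    """Oracle normalization: subtract the analytic ground under each point."""
    z = cloud.z - truth.ground_z(cloud.xy)
    out = cloud.with_xyz(np.column_stack([cloud.x, cloud.y, z]))
    out.meta["normalized"] = True
    return out
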