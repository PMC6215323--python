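"""Shared fixtures: the solved chip model is expensive, so steady and
transient solutions at the stated geometry are computed once per session."""

import numpy as np
import pytest

from oxgradchip.chip_model import (
    ChipGeometry,
    DomainGrid,
    MaterialProps,
    Region,
    build_domain,
    dirichlet,
    NO_FLUX,
    solve_steady_state,
    solve_transient,
)


@pytest.fixture(scope="session")
def chip_domain():
    return build_domain(ChipGeometry(), MaterialProps(), spacing=0.05)


@pytest.fixture(scope="session")
def chip_steady(chip_domain):
    return solve_steady_state(chip_domain, tol=1e-8)


@pytest.fixture(scope="session")
def chip_transient(chip_domain):
    """Uniform 21% start, 48 h horizon, half-hour outputs.

    dt = 120 s keeps the full-horizon run fast; Crank-Nicolson is
    unconditionally stable so the step controls accuracy only, and halving
    it does not change the reported timescales at the output resolution.
    """
    return solve_transient(
        chip_domain, dt_s=120.0, t_end_h=48.0, c_initial=21.0,
        output_interval_h=0.5,
    )


def make_slab(
    lengths_mm, diffusivities_mm2_h, spacing=0.05, c_left=21.0, c_right=0.0
) -> DomainGrid:
    """1D composite slab as a 1-row domain: Dirichlet ends, insulated sides."""
    segments = []
    for L, D in zip(lengths_mm, diffusivities_mm2_h):
        segments.append(np.full(int(round(L / spacing)), D))
    diff = np.concatenate(segments)[None, :]
    region = np.full_like(diff, Region.MEDIUM, dtype=np.int8)
    return DomainGrid(
        spacing=spacing,
        region=region,
        diffusivity=diff,
        edge_bc={
            "left": dirichlet(c_left),
            "right": dirichlet(c_right),
            "top": NO_FLUX,
            "bottom": NO_FLUX,
        },
    )
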