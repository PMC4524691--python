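"""Shared fixtures: scaled-down and default simulations, run directories."""

from __future__ import annotations

import numpy as np
import pytest

from repeatscape.synthetic_data import FamilySpec, SimConfig, simulate_study

SMALL_FAMILIES = (
    FamilySpec("rnd-1_family-1", "LTR/Gypsy", 600, 60, 0.10),
    FamilySpec("rnd-1_family-2", "LTR/Copia", 500, 20, 0.10),
    FamilySpec("rnd-2_family-3", "LINE/L1", 400, 12, 0.12),
    FamilySpec("rnd-3_family-5", "DNA/TcMar-Stowaway", 250, 20, 0.08),
    FamilySpec("rnd-4_family-7", "SINE/tRNA", 150, 12, 0.08),
    FamilySpec("rnd-5_family-8", "Unknown", 400, 16, 0.10),
)


def small_config(seed: int = 7) -> SimConfig:
    """Desk-scale configuration for fast unit/integration tests."""
    return SimConfig(
        seed=seed,
        n_chroms=3,
        chrom_len=70_000,
        families=SMALL_FAMILIES,
        n_genes=36,
        n_mirnas=6,
        mirna_multilocus=2,
        mirna_extra_copies=2,
        mirna_flank_bp=800,
        n_srna_reads=300,
        n_probes=60,
        n_conditions=4,
    )


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(small_config())


@pytest.fixture(scope="session")
def default_study():
    """The default study conditions (used by the recovery suite)."""
    return simulate_study(SimConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
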