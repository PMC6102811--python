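"""Shared fixtures: small simulated libraries built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from amptile.panel import SampleBarcode
from amptile.simulate import (
    ErrorProfile,
    barcode_panel,
    design_tiling,
    make_reference,
    random_barcodes,
    simulate_library,
)


def random_dna(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def small_reference():
    return make_reference(1, 4000, 0.5, homopolymer_spikes=2, seed=7)


@pytest.fixture(scope="session")
def small_designs(small_reference):
    return design_tiling(small_reference, 3, (1400, 1700), (150, 250), seed=1)


@pytest.fixture(scope="session")
def small_samples():
    return [SampleBarcode(f"s{i + 1:02d}", bc)
            for i, bc in enumerate(random_barcodes(2, seed=3))]


@pytest.fixture(scope="session")
def small_panel(small_designs, small_samples):
    return barcode_panel(small_designs, small_samples)


@pytest.fixture(scope="session")
def noisy_library(small_reference, small_designs, small_panel):
    """2 samples x 3 amplicons, depth 6, ~9 passes, ~19 % raw error with
    clean end windows (so clustering is exact-match testable)."""
    profile = ErrorProfile(sub_rate=0.10, ins_rate=0.05, del_rate=0.04,
                           protect_ends=130, seed=11)
    return simulate_library(small_panel, 6, 9.0, profile, None,
                            reference=small_reference, designs=small_designs,
                            seed=5)


@pytest.fixture(scope="session")
def clean_library(small_reference, small_designs, small_panel):
    """Same design, zero sequencing error."""
    profile = ErrorProfile(0.0, 0.0, 0.0, seed=13)
    return simulate_library(small_panel, 3, ("constant", 3), profile, None,
                            reference=small_reference, designs=small_designs,
                            seed=17)
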