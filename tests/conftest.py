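"""Shared fixtures: small random plates and images with injected defects."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cytopls.cleaning import PlateTable


def random_plate(rng, n_samples=4, n_analytes=4, detection_limit=3.2, min_beads=35):
    """A small random long-format plate with every defect class represented.

    Readings mix ordinary triplicates, censored-low values, low-bead wells,
    grossly discordant replicates, and mostly-zero analytes, so the QC
    pipeline and its brute-force oracle are exercised on all branches.
    """
    records = []
    groups = {}
    for s in range(n_samples):
        sid = f"S{s + 1}"
        groups[sid] = "case" if s % 2 else "control"
        for a in range(n_analytes):
            analyte = f"A{a + 1}"
            kind = rng.random()
            base = float(rng.uniform(5, 200))
            if kind < 0.15:  # mostly-zero analyte cell
                vals = rng.uniform(0, detection_limit, 3)
            elif kind < 0.35:  # discordant triplet
                vals = np.array([base, base * (1 + rng.uniform(-0.02, 0.02)), base * 10])
                vals = rng.permutation(vals)
            else:
                vals = base * (1 + rng.uniform(-0.05, 0.05, 3))
            for k in range(3):
                beads = int(rng.integers(5, 30)) if rng.random() < 0.1 else int(
                    rng.integers(min_beads, 150)
                )
                records.append(
                    {
                        "sample_id": sid,
                        "group": groups[sid],
                        "analyte": analyte,
                        "replicate": k + 1,
                        "concentration": float(vals[k]),
                        "bead_count": beads,
                    }
                )
    plate = PlateTable(
        pd.DataFrame.from_records(records),
        detection_limit=detection_limit,
        min_beads=min_beads,
    )
    return plate, groups


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)
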