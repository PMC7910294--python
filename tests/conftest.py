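import numpy as np
import pandas as pd
import pytest

import hcscreen as h
from hcscreen.simulate import zero_noise


@pytest.fixture(scope="session")
def small_config():
    """300 compounds, 30 planted modulators, 10 cytotoxic."""
    return h.SimConfig(n_compounds=300, fraction_modulators=0.1,
                       fraction_cytotoxic=10 / 300, seed=11)


@pytest.fixture(scope="session")
def noiseless_screen(small_config):
    ds, truth = h.simulate_screen(small_config, zero_noise(), tier="primary")
    return ds, truth


@pytest.fixture(scope="session")
def noisy_screen():
    cfg = h.SimConfig(n_compounds=200, fraction_modulators=0.1,
                      fraction_cytotoxic=0.05, seed=7)
    ds, truth = h.simulate_screen(cfg, h.NoiseModel())
    return ds, truth


@pytest.fixture(scope="session")
def reference_curve():
    """An increasing 4PL like an IL-1beta calibration curve."""
    return h.FourPL(bottom=0.0, top=1.0, ec50=0.02, hill=1.0)


def make_summary(cid, activities_ccl2, activities_icam1=None, cell_ratio=1.0):
    """Build one compound-tier summary row from replicate activities."""
    rows = {}
    for ch, acts in (("ccl2", activities_ccl2),
                     ("icam1", activities_icam1 or [1.0] * len(activities_ccl2))):
        acts = np.asarray(acts, float)
        m = acts.mean()
        sd = acts.std(ddof=1) if len(acts) > 1 else np.nan
        rows[f"mean_{ch}"] = m
        rows[f"percent_change_{ch}"] = (m - 1.0) * 100.0
        rows[f"cv_{ch}"] = sd / m * 100.0 if len(acts) > 1 else np.nan
        rows[f"max_change_{ch}"] = float(np.abs(acts - 1.0).max() * 100.0)
    return {"compound_id": cid, "n_rep": len(activities_ccl2),
            "cell_ratio": cell_ratio, **rows}


@pytest.fixture
def summary_builder():
    return make_summary


def tiny_plate(plate_id="P1", stim=(190.0, 210.0), veh=(40.0, 40.0),
               compound_rows=()):
    """A minimal valid plate: 2 vehicle_stim, 2 vehicle_only + compounds.

    ``compound_rows`` are (compound_id, intensity_ccl2, intensity_icam1,
    cell_count) tuples.
    """
    rows = []
    for i, v in enumerate(stim):
        rows.append(dict(plate_id=plate_id, row="A", col=11 + i, role="vehicle_stim",
                         compound_id="", concentration_um=0.0, cell_count=2000,
                         intensity_ccl2=v, intensity_icam1=v))
    for i, v in enumerate(veh):
        rows.append(dict(plate_id=plate_id, row="B", col=11 + i, role="vehicle_only",
                         compound_id="", concentration_um=0.0, cell_count=2000,
                         intensity_ccl2=v, intensity_icam1=v))
    for i, (cid, ic, ii, n) in enumerate(compound_rows):
        rows.append(dict(plate_id=plate_id, row="C", col=1 + i, role="compound",
                         compound_id=cid, concentration_um=10.0, cell_count=n,
                         intensity_ccl2=ic, intensity_icam1=ii))
    return pd.DataFrame(rows)


@pytest.fixture
def plate_builder():
    return tiny_plate
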