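"""Shared fixtures: everything is generated programmatically and seeded.

Heavy objects (the canonical 51 000-bin axis, the synthetic panel, the
simulation design with its extracted backgrounds) are session-scoped because
several modules exercise them.
"""

import numpy as np
import pytest

import aquanmr as aq


@pytest.fixture(scope="session")
def axis():
    return aq.canonical_axis()


@pytest.fixture(scope="session")
def panel():
    """24-target + 4-interferent synthetic panel with DSS."""
    return aq.make_synthetic_library(seed=0, preset="paper_panel")


@pytest.fixture(scope="session")
def panel_concentrations(panel):
    rng = np.random.default_rng(1)
    conc = {e.name: float(rng.uniform(0.5, 2.0)) for e in panel.targets}
    conc |= {e.name: float(rng.uniform(0.5, 1.0)) for e in panel.interferents}
    conc[panel.internal_standard.name] = panel.known_concentration_mM
    return conc


@pytest.fixture(scope="session")
def noiseless_mixture(panel, axis, panel_concentrations):
    return aq.render_mixture(panel, axis, panel_concentrations)


@pytest.fixture(scope="session")
def sim_design(panel):
    design, library = aq.default_simulation_design(seed=0, library=panel)
    return design, library


@pytest.fixture(scope="session")
def sim_report_1e7(sim_design):
    from dataclasses import replace

    design, library = sim_design
    return aq.run_simulation_study(replace(design, lambdas=(1e7,)), library)


@pytest.fixture(scope="session")
def spikein_data():
    return aq.make_spikein_dataset(seed=0)


@pytest.fixture(scope="session")
def spikein_report(spikein_data):
    matrix, blanks, truth, library = spikein_data
    return aq.run_spikein_study(matrix, blanks, truth, library)
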