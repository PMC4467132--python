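import pytest

import mimsim
from mimsim.experiment import Treatment, TreatmentPlan, run_experiment
from mimsim.perturb import PRESET_INHIBITORS, InhibitorSpec


@pytest.fixture(scope="session")
def toy_model():
    return mimsim.make_toy_mim()


@pytest.fixture(scope="session")
def settings():
    return mimsim.SolverSettings()


@pytest.fixture(scope="session")
def physiologic():
    return mimsim.PRESET_GENOTYPES["physiologic"]


@pytest.fixture(scope="session")
def toy_equilibrium(toy_model, settings):
    return mimsim.equilibrate(toy_model, mimsim.initialize_state(toy_model), settings)


@pytest.fixture(scope="session")
def calibrated_strengths(toy_model, physiologic, settings):
    """Mechanistic strengths reproducing each preset's documented level."""
    return {
        name: mimsim.calibrate_inhibitor(
            toy_model, physiologic, PRESET_INHIBITORS[name], settings=settings
        )
        for name in ("CI1040", "Perifosine_20nM", "Perifosine_40nM")
    }


@pytest.fixture(scope="session")
def standard_plan():
    """A spread of single agents and combinations across all three pathways."""
    mek_low = InhibitorSpec("MEKi_low", target="MEKPP",
                            mechanism="activity_scaling", strength=0.35, readout="ERK")
    egfr_half = InhibitorSpec("EGFRi_half", target="EGF.EGFR",
                              mechanism="activity_scaling", strength=0.5, readout="ERK")
    return TreatmentPlan(
        treatments=[
            Treatment("CI1040", ("CI1040",)),
            Treatment("PI103", ("PI103",)),
            Treatment("Perifosine_20nM", ("Perifosine_20nM",)),
            Treatment("Perifosine_40nM", ("Perifosine_40nM",)),
            Treatment("XAV939", ("XAV939",)),
            Treatment("MEKi_low", (mek_low,)),
            Treatment("EGFRi_half", (egfr_half,)),
            Treatment("PI103+CI1040", ("PI103", "CI1040")),
            Treatment("Perifosine_40nM+CI1040", ("Perifosine_40nM", "CI1040")),
        ]
    )


@pytest.fixture(scope="session")
def experiment_table(toy_model, physiologic, standard_plan, settings, calibrated_strengths):
    return run_experiment(
        toy_model, physiologic, standard_plan,
        settings=settings, strengths=dict(calibrated_strengths),
    )


@pytest.fixture(scope="session")
def dose_panel(toy_model, physiologic, settings):
    """Graded MEK x PI3K dose combinations: every endpoint gets a distinct
    prediction per condition, the regime where rank recovery is testable."""
    doses = [(0.15, 0.9), (0.3, 0.75), (0.45, 0.6), (0.6, 0.45),
             (0.75, 0.3), (0.9, 0.15)]
    treatments = [
        Treatment(f"combo{i}", (
            InhibitorSpec(f"MEKi{i}", target="MEKPP",
                          mechanism="activity_scaling", strength=fm),
            InhibitorSpec(f"PI3Ki{i}", target="PI3K_act",
                          mechanism="activity_scaling", strength=fp),
        ))
        for i, (fm, fp) in enumerate(doses)
    ]
    plan = TreatmentPlan(treatments=treatments)
    sim = run_experiment(toy_model, physiologic, plan, settings=settings)
    return plan, sim
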