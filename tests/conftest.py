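import numpy as np
import pytest

import thermoramp as tr


@pytest.fixture(scope="session")
def wt_cohort():
    """Small seed-fixed wild-type cohort (initial sweep only)."""
    proto = tr.RampProtocol(T_peak=57.0, n_sweeps=1)
    return tr.make_cohort("wild_type", 10, 42, protocol=proto)


@pytest.fixture()
def noiseless_params():
    """Quiet single-cell parameters for deterministic checks."""
    return tr.GatingParams(
        dH=330.0,
        dS=330.0e3 / (58.5 + tr.ZERO_C),
        dH_sens=248.0,
        dS_sens=248.0e3 / (56.5 + tr.ZERO_C),
        N_g_max=19.0,
        leak_g=0.35,
        sub_g=0.0,
        noise_sd=0.0,
        sens_rate=0.62,
    )


def arrhenius_current(T_C, Ea_kJ, I0=1000.0, T0_C=40.0):
    """Ideal single-barrier Arrhenius current |I| = I0*exp(-Ea/R * (1/T - 1/T0))."""
    T = np.asarray(T_C) + tr.ZERO_C
    return I0 * np.exp(-Ea_kJ * 1e3 / tr.R_GAS * (1.0 / T - 1.0 / (T0_C + tr.ZERO_C)))
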