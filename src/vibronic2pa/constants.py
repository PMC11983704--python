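"""Physical constants (CODATA 2018) and unit conversions.

All internal computation is done in Hartree atomic units with mass-weighted
coordinates carrying electron-mass weighting; eV, nm, cm^-1 and amu appear
only at I/O boundaries.
"""

import numpy as np

# CODATA 2018
FINE_STRUCTURE = 7.2973525693e-3
BOHR_RADIUS_CM = 0.529177210903e-8
SPEED_OF_LIGHT_CM_S = 2.99792458e10

HARTREE_TO_EV = 27.211386245988
HARTREE_TO_CM1 = 219474.6313632
BOHR_TO_ANGSTROM = 0.529177210903
AMU_TO_ME = 1822.888486209

# hc in eV*nm: photon wavelength [nm] = EV_NM / photon energy [eV]
EV_NM = 1239.841984332

# 1 Goeppert-Mayer = 1e-50 cm^4 s / photon
GM_IN_CM4_S = 1e-50

# default Eq-1-style prefactor (Beerepoot/FCclasses convention)
DEFAULT_PREFACTOR = 4.0 * np.pi**2


def ev_to_hartree(x):
    return np.asarray(x, dtype=float) / HARTREE_TO_EV


def hartree_to_ev(x):
    return np.asarray(x, dtype=float) * HARTREE_TO_EV


def cm1_to_hartree(x):
    return np.asarray(x, dtype=float) / HARTREE_TO_CM1


def hartree_to_cm1(x):
    return np.asarray(x, dtype=float) * HARTREE_TO_CM1
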