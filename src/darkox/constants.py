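"""Physical constants and literature default parameter values.

Everything here is a configuration default: radiochemical yields and
chain energies in particular are inputs a user should review against the
primary literature for their own inventories.
"""

from __future__ import annotations

# fundamental
FARADAY_C_PER_MOL = 96_485.33212        # C mol-1
AVOGADRO = 6.02214076e23                # mol-1
GAS_CONSTANT_J_MOL_K = 8.314462618      # J mol-1 K-1
EV_TO_JOULE = 1.602176634e-19

M_O2_G_PER_MOL = 31.998                 # molecular mass of O2

HOURS_PER_YEAR = 8766.0                 # Julian year, used for h -> yr
SECONDS_PER_DAY = 86_400.0

#: multiplicative pressure response of the optode reading, fraction per 1000 dbar
DEFAULT_PRESSURE_COEFF = 0.032

#: free-solution diffusion coefficient of O2 in seawater at 1.6 degC, S=35
#: (cm2 s-1), interpolated from the tabulation in Schulz & Zabel,
#: Marine Geochemistry (2006), ch. 3.
DEFAULT_D0_O2_CM2_S = 1.18e-5

#: unit factor: flux [mmol m-2 d-1] = porosity * Ds[cm2 s-1] * FICK_UNIT
#: * gradient[µmol l-1 mm-1].  (1 cm2/s = 8.64 m2/d; 1 µmol/l/mm = 1000 mmol/m4.)
FICK_UNIT = 8640.0

# ---------------------------------------------------------------------------
# Radionuclide data.  Half-lives and atomic masses from standard nuclear data
# tables.  ``ea_chain_ev`` is the total energy released per parent decay with
# the full chain in secular equilibrium; ``ea_parent_ev`` is the parent decay
# alone.  ``g_o2`` are literature-derived radiation-chemical yields
# (molecules O2 per 100 eV): half the alpha-radiolysis G(H2) ~1.3 for the
# alpha-dominated chains and half the gamma/beta G(H2) ~0.45 for 40K.
# ---------------------------------------------------------------------------

ISOTOPES = {
    "238U": {
        "half_life_yr": 4.468e9,
        "atomic_mass": 238.0508,
        "ea_chain_ev": 51.7e6,
        "ea_parent_ev": 4.27e6,
        "g_o2": 0.65,
    },
    "235U": {
        "half_life_yr": 7.04e8,
        "atomic_mass": 235.0439,
        "ea_chain_ev": 46.4e6,
        "ea_parent_ev": 4.68e6,
        "g_o2": 0.65,
    },
    "232Th": {
        "half_life_yr": 1.405e10,
        "atomic_mass": 232.0381,
        "ea_chain_ev": 42.6e6,
        "ea_parent_ev": 4.08e6,
        "g_o2": 0.65,
    },
    "40K": {
        "half_life_yr": 1.248e9,
        "atomic_mass": 39.9640,
        "ea_chain_ev": 1.31e6,
        "ea_parent_ev": 1.31e6,
        "g_o2": 0.22,
    },
}

import math as _math

for _d in ISOTOPES.values():
    _d["lambda_per_yr"] = _math.log(2.0) / _d["half_life_yr"]

# ---------------------------------------------------------------------------
# O2 solubility at 1 atm: Garcia & Gordon (1992) refit of the Benson & Krause
# data, coefficient set in ml(STP) l-1; converted to µmol l-1 with the molar
# volume factor 44.6596 µmol per ml(STP).
# ---------------------------------------------------------------------------

GG92_A = (2.00907, 3.22014, 4.05010, 4.94457, -2.56847e-1, 3.88767)
GG92_B = (-6.24523e-3, -7.37614e-3, -1.03410e-2, -8.17083e-3)
GG92_C0 = -4.88682e-7
ML_PER_L_TO_UMOL_PER_L = 44.6596
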