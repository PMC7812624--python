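"""Physical constants for the modified Beer-Lambert law.

Molar extinction coefficients of oxy- and deoxy-hemoglobin at the two
acquisition wavelengths, from the Gratzer/Prahl compiled tabulation
(S. Prahl, "Optical absorption of hemoglobin", OMLC, 1999), in base-10
absorbance units of cm^-1 / (mol/L).  The pipeline's optical density uses
the natural-log convention, so the MBLL multiplies these by ln(10).
"""

import numpy as np

EXTINCTION_CITATION = (
    "Gratzer/Kollias compiled by S. Prahl, OMLC 1999 "
    "(molar extinction, base-10, cm^-1 M^-1)"
)

#: rows: wavelength (760, 850 nm); columns: chromophore (HbO, HbR);
#: units cm^-1 / (mol/L), base-10.
EXTINCTION_M = {
    760.0: (586.0, 1548.52),
    850.0: (1058.0, 691.32),
}


def extinction_matrix(wavelengths_nm=(760.0, 850.0), natural_log=True):
    """Extinction matrix E[w, chromophore] in cm^-1 per microM.

    With ``natural_log=True`` the base-10 tabulated values are scaled by
    ln(10) so that ``dOD_e = E @ [dHbO, dHbR] * d_cm * DPF`` holds for
    natural-log optical density and concentrations in microM.
    """
    rows = []
    for wl in wavelengths_nm:
        if wl not in EXTINCTION_M:
            raise KeyError(f"no extinction tabulated for {wl} nm")
        rows.append(EXTINCTION_M[wl])
    e = np.asarray(rows, dtype=float) * 1e-6  # per microM
    if natural_log:
        e = e * np.log(10.0)
    return e


#: Differential pathlength factors by subject role (adult mother / child).
DPF_BY_ROLE = {"mother": 6.0, "child": 5.5}
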