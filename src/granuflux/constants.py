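"""Physical constants and the unit conventions used across the package.

All interfaces speak mV, mM, s, nm and µm²; SI is used inside flux and
charge arithmetic.  A concentration of 1 mM equals 1 mol/m³, which lets the
simulator track luminal concentrations in mM while dividing mol/s fluxes by
the granule volume in m³.
"""

#: Molar gas constant, J/(mol·K).
R_GAS = 8.31446261815324

#: Faraday constant, C/mol.
FARADAY = 96485.33212

#: Avogadro constant, 1/mol.
N_AVOGADRO = 6.02214076e23

#: Elementary charge, C.
ELEMENTARY_CHARGE = 1.602176634e-19
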