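"""Physical constants and unit conversions used across the package.

Polarizabilities are CGS volume polarizabilities in Å³ throughout; lengths
are Å, molar volumes cm³/mol.
"""

#: Avogadro constant, mol⁻¹.
AVOGADRO = 6.02214e23

#: 1 cm³ expressed in Å³.
CM3_TO_A3 = 1.0e24

#: Monomer residue masses for 2′-deoxynucleotides in an oligonucleotide
#: chain, g/mol.  The oligo mass is the residue sum minus the 5′-OH end
#: correction and one proton per phosphodiester linkage (fully deprotonated
#: polyanion convention).
RESIDUE_MASS = {
    "A": 313.21,
    "C": 289.18,
    "G": 329.21,
    "T": 304.2,
}

#: End-group correction for a 5′-OH oligonucleotide, g/mol.
END_GROUP_MASS = 61.96

#: Mass of one proton removed per internucleotide linkage, g/mol.
PROTON_MASS = 1.008

#: Optical (frequency-dependent) relative permittivity of water at 1312.8 nm.
WATER_EPS_OPTICAL = 1.7485

#: Refractive index of water at 1312.8 nm, 25 °C.
WATER_REFRACTIVE_INDEX = 1.3223

#: Molar volume of water at 25 °C, cm³/mol.
WATER_MOLAR_VOLUME = 18.069

#: Effective cavity-field factor of water for the vdW PCM cavity
#: (energy-effective over effective polarizability ratio).
WATER_CAVITY_FACTOR = 1.1536

#: Default basis-set scaling factor approximating the effect of diffuse
#: functions on oligonucleotide polarizabilities (mean of the two
#: aug-cc-pvdz / cc-pvdz ratios of the dimer and trimer benchmarks).
BASIS_SCALE_FACTOR = 1.1751

#: Wavelength label for the optical Maxwell field used throughout, nm.
WAVELENGTH_NM = 1312.8
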