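# Per-element raw property values used by the carbon-scaled weighting schemes
# (each scheme divides by the carbon row, so w(C) = 1 by construction) and by
# distance-based bond perception.
#
# Columns / provenance:
#   mass            - IUPAC 2021 standard atomic weights (conventional values)
#   covalent_radius - Cordero et al. 2008 single-bond covalent radii, Angstrom
#                     (C: sp3 value)
#   vdw_radius      - Bondi 1964 van der Waals radii, Angstrom (B: Mantina 2009);
#                     the volume scheme uses 4/3*pi*r^3 of these
#   sanderson_en    - Sanderson electronegativities (the scale used by the
#                     Dragon/Todeschini descriptor convention)
#   polarizability  - static average electric dipole polarizabilities,
#                     10^-24 cm^3, CRC Handbook
#   ionization_ev   - first ionization energies, eV, CRC Handbook
element,mass,covalent_radius,vdw_radius,sanderson_en,polarizability,ionization_ev
H,1.008,0.31,1.20,2.592,0.667,13.598
B,10.811,0.84,1.92,2.275,3.03,8.298
C,12.011,0.76,1.70,2.746,1.76,11.260
N,14.007,0.71,1.55,3.194,1.10,14.534
O,15.999,0.66,1.52,3.654,0.802,13.618
F,18.998,0.57,1.47,4.000,0.557,17.423
Si,28.086,1.11,2.10,2.138,5.38,8.152
P,30.974,1.07,1.80,2.515,3.63,10.487
S,32.06,1.05,1.80,2.957,2.90,10.360
Cl,35.45,1.02,1.75,3.475,2.18,12.968
Br,79.904,1.20,1.85,3.219,3.05,11.814
I,126.904,1.39,1.98,2.778,5.35,10.451
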