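# Embedded reference data

## gold_dielectric_jc1972.csv

Complex relative permittivity of gold versus vacuum wavelength, converted
(eps' = n^2 - k^2, eps'' = 2nk) from the experimental refractive-index
compilation of Johnson & Christy, *Phys. Rev. B* **6**, 4370 (1972),
measured on evaporated gold films over photon energies 0.64-6.60 eV
(wavelengths ~188-1937 nm). Values are transcribed from the published table
and rounded; the table is intended for interpolation (monotone PCHIP), not
as a metrology-grade reference. Queries outside the tabulated span raise.

## nuclides.csv

Beta-decay constants used by the dosimetry chain: half-life in hours and
beta endpoint energy in MeV. Au-198: endpoint 0.96 MeV, half-life 2.7 d
(64.8 h). The mean beta energy is not tabulated here; it is computed from
the generated allowed-shape emission spectrum.

## reference_activities_doses_{abstract,results}.csv

Activities (mCi) and absorbed doses (Gy) for the two tumor radii as printed
in two places of the source publication, which disagree with each other.
They are shipped for orientation only and are used nowhere as expected
values: the inputs that would determine them (covering fraction, molecule
density, radioactive atoms per molecule, per-vector footprint) are not
printed, and an independent energy-balance check is inconsistent with both
pairs. See docs/methods.md.
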