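# Bundled cell-line library: 4 rodent and 10 human repair-competent lines.
#
# Each entry feeds build_cell_line(): species constants + karyotype give the
# population-mean DNA content; the nucleus radius comes from a measured value
# or from the DNA-content correlation (from_dna: true); photon_reference sets
# are literature linear-quadratic terms for the reference photon exposure
# (already pooled where several references exist, so a single set with n: 1).
# yD_ref_keV_um defaults to 2.3 (gamma-rays / MV X-rays); switch to 4.3 for
# ~200 kV X-ray references.

C3H10T1/2:
  species: mouse
  karyotype: {p: 2}
  nucleus: {radius_um: 4.0}
  photon_reference: [{alpha: 0.173, beta: 0.0389, n: 1}]
  printed_values:
    beta_ref: 0.389
  notes: >-
    The source table prints beta_ref = 0.389 Gy^-2, which contradicts the
    printed alpha_ref/beta_ref ratio of 4.44 Gy (0.173/4.44 = 0.0389) and
    would make beta0*z_d exceed alpha_ref (negative alpha0). The
    ratio-implied 0.0389 Gy^-2 is used; the printed reading is kept here
    under printed_values rather than silently discarded.

CHO,CHO-K1:
  species: chinese hamster
  karyotype: {p: 2}
  nucleus: {radius_um: 4.2}
  photon_reference: [{alpha: 0.226, beta: 0.0231, n: 1}]

HeLa:
  species: human
  karyotype: {x: 78}
  nucleus: {radius_um: 5.6}
  photon_reference: [{alpha: 0.536, beta: 0.0278, n: 1}]

HF19:
  species: human
  karyotype: {p: 2}
  nucleus: {from_dna: true}
  photon_reference: [{alpha: 0.557, beta: 0.0189, n: 1}]

HL-60:
  species: human
  karyotype: {x: 44}
  nucleus: {from_dna: true}
  photon_reference: [{alpha: 0.315, beta: 0.0558, n: 1}]

M/10:
  species: human
  karyotype: {p: 2}
  nucleus: {from_dna: true}
  photon_reference: [{alpha: 0.3, beta: 0.068, n: 1}]

NB1RGB:
  species: human
  karyotype: {p: 2}
  nucleus: {radius_um: 5.1}
  photon_reference: [{alpha: 0.476, beta: 0.0458, n: 1}]

PDV:
  species: mouse
  karyotype: {x: 62}
  nucleus: {from_dna: true}
  photon_reference: [{alpha: 0.13, beta: 0.037, n: 1}]

RAT-1:
  species: rat
  karyotype: {x: 59}
  nucleus: {from_dna: true}
  photon_reference: [{alpha: 0.201, beta: 0.0266, n: 1}]

SQ20B:
  species: human
  karyotype: {x: 39.3}
  nucleus: {from_dna: true}
  photon_reference: [{alpha: 0.122, beta: 0.0238, n: 1}]
  notes: >-
    No karyotype was found for SQ20B itself; 39.3 chromosomes is a literature
    mean over similar head-and-neck squamous carcinoma lines, taken here as a
    plain input.

T1:
  species: human
  karyotype: {p: 2}
  nucleus: {from_dna: true}
  photon_reference: [{alpha: 0.159, beta: 0.0391, n: 1}]

TK1:
  species: human
  karyotype: {pseudodiploid: true}
  nucleus: {from_dna: true}
  photon_reference: [{alpha: 0.107, beta: 0.0384, n: 1}]

U-87:
  species: human
  karyotype: {x: 39.4}
  nucleus: {from_dna: true}
  photon_reference: [{alpha: 0.106, beta: 0.0557, n: 1}]

U-251MG:
  species: human
  karyotype: {x: 54.6}
  nucleus: {from_dna: true}
  photon_reference: [{alpha: 0.031, beta: 0.0551, n: 1}]
  notes: >-
    Unusually low alpha_ref/beta_ref ratio (~0.56 Gy). With the default
    yD_ref of 2.3 keV/um, beta0*z_d exceeds alpha_ref, so alpha0 from the
    photon decomposition is negative and build_cell_line raises
    InconsistentParametersError: this photon parameter set cannot be
    decomposed into non-negative y->0 limits under the model's constraints.
    The geometric quantities (Rn, rd) are still derivable from the karyotype.
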