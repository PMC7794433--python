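# ATP accounting configuration for the ComX signal peptide, pherotype 168.
#
# Conventions (these reproduce the 484 ATP/molecule total):
#   * residue biosynthesis is charged for the MATURE decapeptide only;
#     the remainder of the 55-residue propeptide is assumed recycled
#     after processing, so its amino-acid synthesis cost is recovered;
#   * polymerization is charged for the FULL precursor: 54 peptide bonds
#     at 4 ATP each (aminoacyl-tRNA charging ATP->AMP = 2 high-energy
#     bonds, + 2 GTP per elongation cycle);
#   * geranylation of the tryptophan costs 30 ATP (geranyl pyrophosphate
#     = 2 isoprene units at ~15 ATP equivalents each).
#
# Residue costs are standard aerobic ATP-equivalent biosynthesis values
# (per molecule) for heterotrophic bacteria.

peptide:
  name: ComX-168
  sequence: ADPITRQWGD          # mature, isoprenylated decapeptide
  precursor_length: 55          # translated propeptide
  modifications:
    - name: geranylation (Trp)
      atp: 30

bond_cost_atp: 4

residue_costs_atp:
  A: 11.7
  R: 27.3
  N: 14.7
  D: 12.7
  C: 24.7
  Q: 16.3
  E: 15.3
  G: 11.7
  H: 38.3
  I: 32.3
  L: 27.3
  K: 30.3
  M: 34.3
  F: 52.0
  P: 20.3
  S: 11.7
  T: 18.7
  W: 74.3
  Y: 50.0
  V: 23.3

# Reference datum (cited, not recomputed): a short acyl-homoserine
# lactone such as C4-HSL costs about 8 ATP per molecule.
reference_ahl_cost_atp: 8
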