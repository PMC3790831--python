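# Default atomic solvation parameters and van der Waals radii.
#
# ASP values are keyed on element class and must be strictly negative.
# These magnitudes are placeholder defaults for testing the engine; the
# docking contracts (surface complementarity reward, overlap penalty,
# restraint weighting) hold for any strictly negative table.  Replace
# with a published solvation parameter set for production use.
asp:
  C: -0.5
  N: -0.2
  O: -0.2
  S: -0.6
  other: -0.2
vdw:
  C: 1.70
  N: 1.55
  O: 1.52
  S: 1.80
  P: 1.80
  other: 1.70
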