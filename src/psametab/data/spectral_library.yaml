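# Chemical-shift library for the synthetic 1H-NMR spectrum renderer.
#
# Per metabolite: a list of multiplets, each with an approximate center
# (ppm, referenced to TSP at 0.00), a relative area (roughly proportional
# to proton count) and a Lorentzian half-width at half-maximum (ppm).
# Values follow standard 500 MHz serum reference compilations but are
# deliberately editable; the pipeline relies only on internal consistency
# of this file, never on literature exactness.
#
# jitter_sd: per-sample, per-multiplet position noise (ppm) emulating
#            pH-driven chemical-shift variation.
# noise_sd:  additive Gaussian baseline noise (intensity units).

jitter_sd: 0.005
noise_sd: 0.002

tsp:
  center: 0.00
  width: 0.0015
  area: 9.0

water:
  center: 4.95
  width: 0.06      # Gaussian SD; band stays inside 4.70-5.20 ppm
  area: 40.0

metabolites:
  2-aminobutyrate:
    - {center: 0.97, area: 3.0, width: 0.002}
    - {center: 1.89, area: 2.0, width: 0.002}
    - {center: 3.71, area: 1.0, width: 0.002}
  alanine:
    - {center: 1.47, area: 3.0, width: 0.002}
    - {center: 3.77, area: 1.0, width: 0.002}
  anserine:
    - {center: 2.66, area: 2.0, width: 0.002}
    - {center: 3.21, area: 2.0, width: 0.002}
    - {center: 7.09, area: 1.0, width: 0.002}
    - {center: 8.20, area: 1.0, width: 0.002}
  glucose:
    - {center: 3.24, area: 1.0, width: 0.0025}
    - {center: 3.41, area: 2.0, width: 0.0025}
    - {center: 3.53, area: 1.0, width: 0.0025}
    - {center: 3.72, area: 2.0, width: 0.0025}
    - {center: 3.84, area: 1.0, width: 0.0025}
    - {center: 4.64, area: 0.6, width: 0.002}
    - {center: 5.23, area: 0.4, width: 0.002}
  glutamine:
    - {center: 2.13, area: 2.0, width: 0.0025}
    - {center: 2.45, area: 2.0, width: 0.0025}
    - {center: 3.77, area: 1.0, width: 0.002}
  glycylproline:
    - {center: 2.03, area: 3.0, width: 0.0025}
    - {center: 2.31, area: 1.0, width: 0.0025}
    - {center: 3.62, area: 2.0, width: 0.002}
    - {center: 4.12, area: 1.0, width: 0.002}
  isoleucine:
    - {center: 0.93, area: 3.0, width: 0.002}
    - {center: 1.00, area: 3.0, width: 0.002}
    - {center: 1.46, area: 1.0, width: 0.002}
    - {center: 1.97, area: 1.0, width: 0.002}
    - {center: 3.66, area: 1.0, width: 0.002}
  leucine:
    - {center: 0.95, area: 6.0, width: 0.002}
    - {center: 1.70, area: 3.0, width: 0.002}
    - {center: 3.73, area: 1.0, width: 0.002}
  methionine:
    - {center: 2.13, area: 3.0, width: 0.002}
    - {center: 2.64, area: 2.0, width: 0.002}
    - {center: 3.85, area: 1.0, width: 0.002}
  serine:
    - {center: 3.83, area: 1.0, width: 0.002}
    - {center: 3.94, area: 2.0, width: 0.002}
  threonate:
    - {center: 3.74, area: 1.0, width: 0.002}
    - {center: 4.02, area: 1.0, width: 0.002}
    - {center: 4.31, area: 1.0, width: 0.002}
  tryptophan:
    - {center: 3.31, area: 1.0, width: 0.002}
    - {center: 4.05, area: 1.0, width: 0.002}
    - {center: 7.28, area: 1.0, width: 0.002}
    - {center: 7.54, area: 1.0, width: 0.002}
    - {center: 7.73, area: 1.0, width: 0.002}
  valine:
    - {center: 0.98, area: 3.0, width: 0.002}
    - {center: 1.04, area: 3.0, width: 0.002}
    - {center: 2.26, area: 1.0, width: 0.002}
    - {center: 3.60, area: 1.0, width: 0.002}
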