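# Walnut Creek (WNT5 subwatershed, Jasper County, Iowa) case study:
# 41% of the subwatershed converted from row crop to native prairie,
# predominantly in a random spatial pattern.
#
# The legacy soil-organic-N stock is 100 kg/ha of readily mineralizable N
# over the 1 m soil profile (about 6 kg/ha/y accumulated over seven decades
# of intensive row-crop agriculture, of which roughly a quarter is readily
# mineralizable; areal mass, not per square metre).  The exponential
# travel-time distribution (mean 21.6 y) comes from a calibrated groundwater
# flow model of the site; the denitrification band 0.24 +/- 0.08 1/y is
# typical of shallow aquifers in glacial till and outwash.
source_zone:
  mson0_kg_per_ha: 100.0
  cs0_mg_per_L: 15.0
  lambda_per_y: 0.16
  recharge_mm_per_y: 129.5
  saturation: 0.5
  porosity: 0.3
  depth_m: 1.0
ttd:
  kind: exponential
  mu_years: 21.6
denitrification:
  k_per_y:
    low: 0.16
    mid: 0.24
    high: 0.32
scenario:
  pattern: random
  p: 0.41
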