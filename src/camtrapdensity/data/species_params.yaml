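# Default movement parameters per species.
#
# Step lengths/SDs in metres, angular-deflection SD in degrees, activity
# as steps per month, home range in km² (mean of published estimates;
# for the pooled foxes this averages culpeo and gray-fox values).
"Lycalopex spp.":
  mean_step_m: 13.18
  sd_step_m: 17.31
  sd_turn_deg: 26.31
  steps_per_month: 5000
  home_range_km2: 5.31
"Leopardus guigna":
  mean_step_m: 19.03
  sd_step_m: 13.07
  sd_turn_deg: 41.04
  steps_per_month: 3000
  home_range_km2: 4.85
"Conepatus chinga":
  mean_step_m: 12.77
  sd_step_m: 15.16
  sd_turn_deg: 52.12
  steps_per_month: 4000
  home_range_km2: 1.614
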