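# Nearest-neighbour free energy parameters, kcal/mol at 37 C.
# Compact table: helix stacking by pair/pair, loop initiation by size,
# affine multiloop. No dangling ends, no coaxial stacking, no
# sequence-dependent loop bonuses.
#
# stack <5'pair> <3'pair> <dG>
#   5'pair = (s_i, s_j) closing pair, 3'pair = (s_i+1, s_j-1) stacked pair,
#   both written 5'base+3'base.
stack CG CG -2.40
stack CG GC -3.30
stack CG GU -2.10
stack CG UG -1.40
stack CG AU -2.10
stack CG UA -2.10
stack GC CG -3.30
stack GC GC -3.40
stack GC GU -2.50
stack GC UG -1.50
stack GC AU -2.20
stack GC UA -2.40
stack GU CG -2.10
stack GU GC -2.50
stack GU GU 1.30
stack GU UG -0.50
stack GU AU -1.40
stack GU UA -1.30
stack UG CG -1.40
stack UG GC -1.50
stack UG GU -0.50
stack UG UG 0.30
stack UG AU -0.60
stack UG UA -1.00
stack AU CG -2.10
stack AU GC -2.20
stack AU GU -1.40
stack AU UG -0.60
stack AU AU -1.10
stack AU UA -0.90
stack UA CG -2.10
stack UA GC -2.40
stack UA GU -1.30
stack UA UG -1.00
stack UA AU -0.90
stack UA UA -1.30
# hairpin <size> <dG>  (size = unpaired positions; larger sizes extrapolated)
hairpin 3 5.40
hairpin 4 5.60
hairpin 5 5.70
hairpin 6 5.40
hairpin 7 6.00
hairpin 8 5.50
hairpin 9 6.40
hairpin 10 6.50
# bulge <size> <dG>
bulge 1 3.80
bulge 2 2.80
bulge 3 3.20
bulge 4 3.60
bulge 5 4.00
bulge 6 4.40
# internal <total unpaired> <dG>
internal 2 1.50
internal 3 1.60
internal 4 1.70
internal 5 1.80
internal 6 2.00
# multiloop closing / per-branch / per-unpaired-nt terms
multiloop closing 3.40
multiloop branch 0.40
multiloop unpaired 0.00
# Jacobson-Stockmayer extrapolation slope (1.75 * RT at 37 C)
extrapolation 1.079
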