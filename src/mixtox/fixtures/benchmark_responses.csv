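readout,is_incidence,worm_type,day,direction,bmr
lethality,1,adult,7,+,10
lethality,1,adult,12,+,20
lethality,1,regenerating,7,+,10
lethality,1,regenerating,12,+,15
stickiness,1,adult,7,+,50
stickiness,1,adult,12,+,50
stickiness,1,regenerating,7,+,50
stickiness,1,regenerating,12,+,50
speed_dark,0,adult,7,+,50
speed_dark,0,adult,7,-,50
speed_dark,0,adult,12,+,40
speed_dark,0,adult,12,-,50
speed_dark,0,regenerating,7,+,35
speed_dark,0,regenerating,7,-,30
speed_dark,0,regenerating,12,+,45
speed_dark,0,regenerating,12,-,45
resting_dark,0,adult,7,+,65
resting_dark,0,adult,7,-,40
resting_dark,0,adult,12,+,45
resting_dark,0,adult,12,-,55
resting_dark,0,regenerating,7,+,35
resting_dark,0,regenerating,7,-,60
resting_dark,0,regenerating,12,+,50
resting_dark,0,regenerating,12,-,55
speed_blue,0,adult,7,+,55
speed_blue,0,adult,7,-,50
speed_blue,0,adult,12,+,45
speed_blue,0,adult,12,-,50
speed_blue,0,regenerating,7,+,40
speed_blue,0,regenerating,7,-,40
speed_blue,0,regenerating,12,+,70
speed_blue,0,regenerating,12,-,40
resting_blue,0,adult,7,+,35
resting_blue,0,adult,7,-,30
resting_blue,0,adult,12,+,30
resting_blue,0,adult,12,-,40
resting_blue,0,regenerating,7,+,35
resting_blue,0,regenerating,7,-,35
resting_blue,0,regenerating,12,+,40
resting_blue,0,regenerating,12,-,40
wall_preference,0,adult,7,-,35
wall_preference,0,adult,12,-,25
wall_preference,0,regenerating,7,-,40
wall_preference,0,regenerating,12,-,35
locomotor_bursts,0,adult,7,+,11
locomotor_bursts,0,adult,7,-,7
locomotor_bursts,0,adult,12,+,11
locomotor_bursts,0,adult,12,-,6
locomotor_bursts,0,regenerating,7,+,18
locomotor_bursts,0,regenerating,7,-,11
locomotor_bursts,0,regenerating,12,+,9
locomotor_bursts,0,regenerating,12,-,6
phototaxis,0,adult,7,+,35
phototaxis,0,adult,7,-,45
phototaxis,0,adult,12,+,30
phototaxis,0,adult,12,-,40
phototaxis,0,regenerating,7,+,30
phototaxis,0,regenerating,7,-,20
phototaxis,0,regenerating,12,+,35
phototaxis,0,regenerating,12,-,35
thermotaxis,0,adult,12,-,45
thermotaxis,0,regenerating,12,-,40
scrunching,1,adult,12,+,25
scrunching,1,regenerating,12,+,50
noxious_rate,0,adult,12,+,35
noxious_rate,0,adult,12,-,25
noxious_rate,0,regenerating,12,+,35
noxious_rate,0,regenerating,12,-,30
noxious_strength,0,adult,12,+,50
noxious_strength,0,adult,12,-,65
noxious_strength,0,regenerating,12,+,50
noxious_strength,0,regenerating,12,-,65
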