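# Synthetic stand-in for a 77-term anaphylaxis SMQ (one code per line).
anaphylaxis
anaphylactic_reaction
anaphylactic_shock
generalized_urticaria
generalized_erythema
angioedema
generalized_pruritus
skin_rash
localized_injection_site_urticaria
measured_hypotension
tachycardia
bilateral_wheeze
stridor
upper_airway_swelling
difficulty_breathing
difficulty_breathing_without_wheeze_or_stridor
sensation_of_throat_closure
hoarse_voice
cyanosis
nausea
vomiting
diarrhea
sneezing_rhinorrhea
SYN:000001
SYN:000002
SYN:000003
SYN:000004
SYN:000005
SYN:000006
SYN:000007
SYN:000008
SYN:000009
SYN:000010
SYN:000011
SYN:000012
SYN:000013
SYN:000014
SYN:000015
SYN:000016
SYN:000017
SYN:000018
SYN:000019
SYN:000020
SYN:000021
SYN:000022
SYN:000023
SYN:000024
SYN:000025
SYN:000026
SYN:000027
SYN:000028
SYN:000029
SYN:000030
SYN:000031
SYN:000032
SYN:000033
SYN:000034
SYN:000035
SYN:000036
SYN:000037
SYN:000038
SYN:000039
SYN:000040
SYN:000041
SYN:000042
SYN:000043
SYN:000044
SYN:000045
SYN:000046
SYN:000047
SYN:000048
SYN:000049
SYN:000050
SYN:000051
SYN:000052
SYN:000053
SYN:000054
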