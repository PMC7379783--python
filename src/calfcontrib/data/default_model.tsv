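# Default calf musculoskeletal model (reduced foot-shank subsystem).
#
# Sign conventions (fixed for the whole package):
#   ankle_flexion : dorsiflexion positive, plantarflexion negative
#   subtalar      : inversion positive, eversion negative
#   mtp_flexion   : toe extension positive, toe flexion negative
#
# The maximum isometric forces and constant moment arms below are
# literature-typical surrogate values, NOT measured parameters; they are
# configurable priors and every entry may be overridden by supplying a
# custom model file of the same layout.  Units: newtons and metres.
[dofs]
ankle_flexion
subtalar
mtp_flexion
[muscles]
muscle	group	f_max_N	r_ankle_m	r_subtalar_m	r_mtp_m
Tibialis anterior	dorsiflexor	905	0.040	0.012	0
Extensor hallucis longus	toe extensor	165	0.035	0.005	0.012
Extensor digitorum longus 1st	toe extensor	115	0.032	-0.010	0.010
Extensor digitorum longus 2nd	toe extensor	115	0.032	-0.010	0.010
Extensor digitorum longus 3rd	toe extensor	115	0.032	-0.010	0.010
Fibularis peroneus brevis	evertor	500	-0.005	-0.024	0
Gastrocnemius lateralis	plantarflexor	700	-0.047	0	0
Gastrocnemius medialis	plantarflexor	1500	-0.047	0	0
Soleus	plantarflexor	3500	-0.049	0.002	0
Flexor hallucis longus	toe flexor	700	-0.038	0.008	-0.030
Flexor digitorum longus 1st	toe flexor	150	-0.036	0.008	-0.022
Flexor digitorum longus 2nd	toe flexor	150	-0.036	0.008	-0.022
Flexor digitorum longus 3rd	toe flexor	150	-0.036	0.008	-0.022
Tibialis posterior 1st	invertor	400	-0.030	0.018	0
Tibialis posterior 2nd	invertor	400	-0.030	0.018	0
Tibialis posterior 3rd	invertor	400	-0.030	0.018	0
Tibialis posterior 4th	invertor	400	-0.030	0.018	0
[segments]
segment	mass_fraction	com_offset_m	gyration_radius_m
foot	0.0137	0.050	0.055
shank	0.0433	0.190	0.150
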