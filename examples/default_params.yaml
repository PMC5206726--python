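egf_gain: 0.015423562818497275
k_egfr_deact: 0.5
b1: 1.0
u1: 1.0
bG: 2.0
uG: 1.0
bT: 20.0
uT: 1.0
k2A: 60.0
k2B: 6.0
k2C: 0.0
b3: 1600.0
u3: 1.0
k_raf_act: 2.0
k_raf_deact: 0.5
k_mek_ph: 4.0
k_mek_deph: 0.5
k_erk_ph: 4.0
k_erk_deph: 0.5
q1: 0.465
d1: 0.1
q2: 0.05
d2: 0.05
q3: 0.05
d3: 0.05
f_nf1: 1.0
f_nf2: 1.0
f_nf3: 1.0
nf2_targets_active: true
n_sos_sites: 4
EGFR_tot: 1.0
SOS_tot: 0.05
RAS_tot: 1.0
RasGAP_tot: 0.05
RAF_tot: 1.0
MEK_tot: 1.0
ERK_tot: 1.0
reporters:
  EKAR3:
    k_ph: 0.5
    k_deph: 0.15
    total: 0.01
  ERKTR:
    k_ph: 5.0
    k_deph: 1.5
    total: 0.01
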