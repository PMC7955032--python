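>construct_mripk3_synthetic | mouse RIPK3 RHIM construct STAND-IN (86 aa, avg mass 9.57 kDa) | SYNTHETIC: the rigid-core region 440-461 follows the experimentally characterized sequence (strand segments 441-444/448-452/454-460, arc 445-447, RHIM tetrad 448-VQIG-451); the His-tag leader (numbered 401-408) and the flanking regions 409-439/462-486, which are disordered and invisible in the fibril core, are synthetic filler chosen to reproduce the construct's documented length and average molecular mass. Not the deposited sequence.
MGHHHHHHSPLREQFKDVTGALNSWEPQMIRSDTKEAGLLVFNNCSEVQIGNYNSLVTSPG
TKSEPLVRGDQFANSIEPMTGKSLE
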