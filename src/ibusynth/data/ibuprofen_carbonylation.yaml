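# Reconstructed Pd-carbonylation network for ibuprofen synthesis.
# Tracked species (mol/m^3): substrate alcohol (roh), alkene (ren), benzylic
# chloride (rcl), product (ibu), ibuprofen-substrate ester (ester), H+ (hp),
# Cl- (cl), water (h2o), and the four Pd pools pd1 (L2PdCl2 precursor),
# pd2 (activated catalyst), pd3 (oxidative-addition adduct), pd4 (acyl
# complex after CO insertion).  Dissolved CO is held at a fixed
# concentration; gas-phase saturation is absorbed into k6.
# Kinetic orders are forced by the rate-constant units: total order 2 for
# m^3/(s mol) constants, order 3 for m^6/(s mol^2).
species: [roh, ren, rcl, ibu, ester, hp, cl, h2o, pd1, pd2, pd3, pd4]
constant_species:
  co: 1.0
rate_constants: [k1, k2, k3, k4, k5, k6, k7, k8f, k8r]
reactions:
  - name: r1            # acid-catalysed dehydration: roh -> ren + H2O
    orders: {roh: 1, hp: 1}
    stoichiometry: {roh: -1, ren: 1, h2o: 1}
    rate_constant: k1
  - name: r2            # hydrohalogenation: ren + H+ + Cl- -> rcl
    orders: {ren: 1, hp: 1, cl: 1}
    stoichiometry: {ren: -1, hp: -1, cl: -1, rcl: 1}
    rate_constant: k2
  - name: r3            # dehydrohalogenation: rcl + H2O -> ren + H+ + Cl-
    orders: {rcl: 1, h2o: 1}
    stoichiometry: {rcl: -1, h2o: -1, ren: 1, hp: 1, cl: 1}
    rate_constant: k3
  - name: r4            # catalyst activation: pd1 + H2O -> pd2 + 2H+ + 2Cl-
    orders: {pd1: 1, h2o: 2}
    stoichiometry: {pd1: -1, h2o: -1, pd2: 1, hp: 2, cl: 2}
    rate_constant: k4
  - name: r5            # oxidative addition: rcl + pd2 -> pd3
    orders: {rcl: 1, pd2: 1}
    stoichiometry: {rcl: -1, pd2: -1, pd3: 1}
    rate_constant: k5
  - name: r6            # carbonylation: pd3 + CO -> pd4
    orders: {pd3: 1, co: 1}
    stoichiometry: {pd3: -1, pd4: 1}
    rate_constant: k6
  - name: r7            # hydrolysis: pd4 + H2O -> ibu + pd2 + H+ + Cl-
    orders: {pd4: 1, h2o: 1}
    stoichiometry: {pd4: -1, h2o: -1, ibu: 1, pd2: 1, hp: 1, cl: 1}
    rate_constant: k7
  - name: r8f           # esterification: ibu + roh (H+ cat.) -> ester + H2O
    orders: {ibu: 1, roh: 1, hp: 1}
    stoichiometry: {ibu: -1, roh: -1, ester: 1, h2o: 1}
    rate_constant: k8f
  - name: r8r           # ester hydrolysis: ester + H2O (H+ cat.) -> ibu + roh
    orders: {ester: 1, h2o: 1, hp: 1}
    stoichiometry: {ester: -1, h2o: -1, ibu: 1, roh: 1}
    rate_constant: k8r
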