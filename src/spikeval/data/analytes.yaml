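# Default analyte panel for the coca-leaf alkaloid oral-fluid GC-MS method.
#
# SIM ions and retention-group start times follow the published acquisition
# method; the first listed ion is the quantifier. logP values for the five
# calibrated targets are the published octanol/water partition coefficients;
# HYG and SKF carry estimated values (no published figure) used only by the
# pad-retention simulator, never by a validation statistic. Deuterated
# analogues share the parent's logP.
analytes:
  - name: HYG
    role: target
    logP: 0.8          # estimate; no published value
    quant_ion: 84
    qualifier_ions: [42, 141]
    retention_group_start: 5.00
    assigned_is: EME-d3
  - name: EME
    role: target
    logP: -0.23
    quant_ion: 96
    qualifier_ions: [82, 94]
    retention_group_start: 7.50
    assigned_is: EME-d3
  - name: EME-d3
    role: deuterated_IS
    logP: -0.23
    quant_ion: 99
    qualifier_ions: [85]
    retention_group_start: 7.50
  - name: CUS
    role: target
    logP: 0.72
    quant_ion: 84
    qualifier_ions: [42, 209]
    retention_group_start: 7.50
    assigned_is: EME-d3
  - name: TRO
    role: target
    logP: 2.6
    quant_ion: 124
    qualifier_ions: [82, 245]
    retention_group_start: 7.50
    assigned_is: COC-d3
  - name: COC
    role: target
    logP: 2.6
    quant_ion: 182
    qualifier_ions: [198, 303]
    retention_group_start: 12.50
    assigned_is: COC-d3
  - name: COC-d3
    role: deuterated_IS
    logP: 2.6
    quant_ion: 185
    qualifier_ions: [306]
    retention_group_start: 12.50
  - name: SKF
    role: external_standard
    logP: 5.2          # estimate; no published value
    quant_ion: 86
    qualifier_ions: [99]
    retention_group_start: 12.50
  - name: t-CIN
    role: target
    logP: 2.7
    quant_ion: 96
    qualifier_ions: [103, 182, 329]
    retention_group_start: 15.10
    assigned_is: COC-d3
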