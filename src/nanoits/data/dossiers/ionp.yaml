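# Dextran-coated iron-oxide nanoparticle medical device (multicore
# magnetite/maghemite assemblies in a dextran matrix).  The asserted
# classes are the minimal knowledge that drives the published filtering
# outcome for the particle-size endpoint: metal-oxide classification,
# high polydispersity, a size window compatible with tracking analysis.
schema_version: "1.0"
name: BK-MNP
description: Aqueous suspension of dextran-coated iron-oxide multicore nanoassemblies.
product_type: medical_device
md_props:
  device_category: class_iii
  contact_type: circulating_blood
  contact_duration: limited
components:
  - name: magnetite_core
    category: generic
    layers: [core]
    cas_number: 1317-61-9
  - name: maghemite_core
    category: generic
    layers: [core]
    cas_number: 1309-37-1
  - name: dextran_matrix
    category: generic
    layers: [coating]
    cas_number: 9004-54-0
facts:
  nm:
    classes:
      formulation: liquid
      particle_classification: metal_oxide
      particle_size_lower: mid_low
      polydispersity: high
      refractive_index: high_ri
measurements: {}
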