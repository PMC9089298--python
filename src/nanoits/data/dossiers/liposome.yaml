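# PEGylated liposomal doxorubicin (the first approved nano-enabled
# medicinal product), administered intravenously.
schema_version: "1.0"
name: Doxil
description: PEGylated liposome encapsulating doxorubicin in a liquid-ordered bilayer.
product_type: medicinal_product
mp_props:
  clinical_indication: oncology
  administration_route: intravenous
components:
  - name: doxorubicin
    category: api
    layers: [core]
    cas_number: 25316-40-9
  - name: phosphatidylcholine
    category: excipient
    layers: [shell]
  - name: cholesterol
    category: excipient
    layers: [shell]
    cas_number: 57-88-5
  - name: mpeg_dspe
    category: excipient
    layers: [coating]
facts:
  nm:
    classes:
      formulation: liquid
      particle_classification: liposomal
      particle_size_lower: mid_high
      polydispersity: low
      refractive_index: low_ri
measurements: {}
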