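# Poly(alkylcyanoacrylate) nanoparticle medicinal product: PEBCA polymer
# carrier encapsulating cabazitaxel, injected intravenously.
schema_version: "1.0"
name: PEBCA-cabazitaxel
description: Poly(ethylbutyl cyanoacrylate) nanoparticles encapsulating cabazitaxel.
product_type: medicinal_product
mp_props:
  clinical_indication: oncology
  administration_route: intravenous
components:
  - name: cabazitaxel
    category: api
    layers: [core]
    cas_number: 183133-96-2
  - name: pebca_polymer
    category: excipient
    layers: [core, shell]
facts:
  nm:
    classes:
      formulation: liquid
      particle_classification: polymeric
      particle_size_lower: mid_high
      polydispersity: low
measurements: {}
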