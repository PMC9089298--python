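# Iron-carbohydrate medicinal product (ferumoxytol): maghemite core with a
# carbohydrate coating, administered intravenously.  Size is asserted in the
# smallest class (< 30 nm) so both branches of the tracking-analysis rule
# fail on the size atoms; the refractive index is left unassigned.
schema_version: "1.0"
name: Feraheme
description: Ferumoxytol iron replacement product; iron-oxide core with carbohydrate coating.
product_type: medicinal_product
mp_props:
  clinical_indication: iron_deficiency_anemia
  administration_route: intravenous
components:
  - name: ferumoxytol_core
    category: api
    layers: [core]
    cas_number: 1309-37-1
  - name: carbohydrate_coating
    category: excipient
    layers: [coating]
facts:
  nm:
    classes:
      formulation: liquid
      particle_classification: metal_oxide
      particle_size_lower: small
      polydispersity: low
measurements: {}
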