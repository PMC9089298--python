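# The "empty" case study: a product with no nanomaterial knowledge at all.
# With every endpoint unassigned, every applicability rule is UNKNOWN and
# the full assay catalogue is proposed.
schema_version: "1.0"
name: Empty case study
description: No prior characterization or classification knowledge.
product_type: medicinal_product
mp_props:
  clinical_indication: other
  administration_route: intravenous
components: []
facts: {}
measurements: {}
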