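# Default knowledge base: the printed class bins and applicability rules
# for the physicochemical and immunotoxicity modules.
#
# Quantitative bins are left-closed/right-open ([lo, hi)) unless flagged;
# the neutral surface-charge class owns both of its +/-10 mV boundaries so
# the positive/negative classes keep their strict inequalities.
#
# Characteristic profiles (duration/cost/resolution/expertise) and the
# numeric rule thresholds that are not fixed by the published class bins
# (SLS minimum size, DLS polydispersity cut, PDI bins) are fixture choices,
# constrained so that (a) DLS and SLS rank first among the particle-size
# assays and (b) the four case-study filtering outcomes are reproduced.
schema_version: "1.0"

modules:
  - id: physicochemical
    label: Physicochemical characterization
    product_scope: [medical_device, medicinal_product]
  - id: immunotoxicity
    label: Immunotoxicity
    product_scope: [medical_device, medicinal_product]
  - id: product_profile
    label: Product-level descriptors
    product_scope: [medical_device, medicinal_product]

endpoints:
  # --- product-level descriptors (facts come from the dossier header) ---
  - id: route_of_administration
    module: product_profile
    label: Route of administration
    kind: qualitative
    classes: [dermal, intravenous, oral, subcutaneous, inhalation]
  - id: dermal_systemic_exposure
    module: product_profile
    label: Dermal systemic exposure
    kind: qualitative
    classes: ["yes", "no"]
  - id: clinical_indication
    module: product_profile
    label: Clinical indication
    kind: qualitative
    classes: [oncology, iron_deficiency_anemia, infection, other]
  - id: device_category
    module: product_profile
    label: Device category
    kind: qualitative
    classes: [class_i, class_iia, class_iib, class_iii]
  - id: contact_type
    module: product_profile
    label: Contact type
    kind: qualitative
    classes: [intact_skin, mucosal_membrane, blood_path, tissue_bone_dentin, circulating_blood]
  - id: contact_duration
    module: product_profile
    label: Contact duration
    kind: qualitative
    classes: [limited, prolonged, permanent]

  # --- physicochemical ---
  - id: particle_size_lower
    module: physicochemical
    label: Particle size diameter (lower bound)
    kind: quantitative
    unit: nm
    domain: {lower: 0, upper: 10000, lower_inclusive: false, upper_inclusive: true}
    classes:
      - {label: small, upper: 30}
      - {label: mid_low, lower: 30, upper: 60}
      - {label: mid_high, lower: 60, upper: 200}
      - {label: big, lower: 200}
  - id: polydispersity
    module: physicochemical
    label: Polydispersity index (PDI)
    kind: quantitative
    unit: ""
    domain: {lower: 0, upper: 1, lower_inclusive: true, upper_inclusive: true}
    classes:
      - {label: low, upper: 0.1}
      - {label: medium, lower: 0.1, upper: 0.3}
      - {label: high, lower: 0.3}
  - id: surface_charge
    module: physicochemical
    label: Surface charge (zeta potential)
    kind: quantitative
    unit: mV
    domain: {lower: -200, upper: 200, lower_inclusive: true, upper_inclusive: true}
    classes:
      - {label: negative, upper: -10}
      - {label: neutral, lower: -10, upper: 10, upper_inclusive: true}
      - {label: positive, lower: 10, lower_inclusive: false}
  - id: refractive_index
    module: physicochemical
    label: Refractive index
    kind: quantitative
    unit: ""
    domain: {lower: 1, upper: 5, lower_inclusive: true, upper_inclusive: true}
    classes:
      - {label: low_ri, upper: 1.6}
      - {label: high_ri, lower: 1.6}
  - id: formulation
    module: physicochemical
    label: Formulation
    kind: qualitative
    classes: [liquid, powder]
  - id: particle_classification
    module: physicochemical
    label: Particle classification
    kind: qualitative
    classes: [metal_oxide, polymeric, liposomal, lipid_based, protein_based, other]

  # --- immunotoxicity ---
  - id: skin_sensitisation
    module: immunotoxicity
    label: Skin sensitisation
    kind: qualitative
    classes: ["yes", "no"]
  - id: sts_haematological_changes
    module: immunotoxicity
    label: STS - haematological changes
    kind: qualitative
    classes: [present, absent]
  - id: affects_immune_function
    module: immunotoxicity
    label: Affects immune function
    kind: qualitative
    classes: ["yes", "no"]

assays:
  - id: dls
    name: Dynamic light scattering (DLS)
    module: physicochemical
    measures: [particle_size_lower, polydispersity, surface_charge]
    characteristics: {duration: low, cost: low, resolution: low, expertise: low}
    applicability:
      and:
        - atom: {form: range_within, endpoint: particle_size_lower, lower: 0, upper: 1000}
        - not:
            atom: {form: class_is, endpoint: polydispersity, class: high}
  - id: sls
    name: Static light scattering (SLS)
    module: physicochemical
    measures: [particle_size_lower]
    characteristics: {duration: low, cost: low, resolution: low, expertise: medium}
    applicability:
      atom: {form: range_within, endpoint: particle_size_lower, lower: 60, upper: 10000}
  - id: nta
    name: Nanoparticle tracking analysis (NTA)
    module: physicochemical
    measures: [particle_size_lower]
    characteristics: {duration: medium, cost: medium, resolution: low, expertise: medium}
    applicability:
      or:
        - and:
            - atom: {form: class_is, endpoint: refractive_index, class: low_ri}
            - atom: {form: range_within, endpoint: particle_size_lower, lower: 60, upper: 1000}
        - and:
            - atom: {form: class_is, endpoint: refractive_index, class: high_ri}
            - atom: {form: range_within, endpoint: particle_size_lower, lower: 30, upper: 1000}
  - id: sec_uv_vis_ri
    name: SEC-UV-VIS/RI (size-exclusion chromatography)
    module: physicochemical
    measures: [particle_size_lower]
    characteristics: {duration: medium, cost: medium, resolution: low, expertise: high}
    applicability:
      not:
        atom: {form: class_is, endpoint: particle_classification, class: metal_oxide}
  - id: cf3_uv_vis_ri
    name: CF3-UV-VIS/RI (centrifugal field-flow fractionation)
    module: physicochemical
    measures: [particle_size_lower]
    characteristics: {duration: high, cost: medium, resolution: low, expertise: high}
    applicability:
      not:
        atom: {form: class_is, endpoint: particle_classification, class: metal_oxide}
  - id: af4_uv_vis_ri
    name: AF4-UV-VIS/RI (asymmetric-flow field-flow fractionation)
    module: physicochemical
    measures: [particle_size_lower]
    characteristics: {duration: high, cost: high, resolution: low, expertise: high}
    applicability:
      not:
        atom: {form: class_is, endpoint: particle_classification, class: metal_oxide}
  - id: ldm_electrophoresis
    name: Laser Doppler micro-electrophoresis
    module: physicochemical
    measures: [surface_charge]
    characteristics: {duration: low, cost: low, resolution: medium, expertise: low}
  - id: oecd_442c
    name: OECD TG 442C in chemico skin sensitisation (DPRA)
    module: immunotoxicity
    measures: [skin_sensitisation]
    characteristics: {duration: medium, cost: low, resolution: medium, expertise: medium}
    applicability:
      and:
        - atom: {form: class_is, endpoint: route_of_administration, class: dermal}
        - atom: {form: class_is, endpoint: dermal_systemic_exposure, class: "no"}
  - id: haematology_panel
    name: Standard haematology panel
    module: immunotoxicity
    measures: [sts_haematological_changes]
    characteristics: {duration: low, cost: low, resolution: medium, expertise: low}

module_selection_rules:
  - target: skin_sensitisation
    rule:
      and:
        - atom: {form: class_is, endpoint: route_of_administration, class: dermal}
        - atom: {form: class_is, endpoint: dermal_systemic_exposure, class: "no"}
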