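# nanoits

Rule-based intelligent testing strategies (ITS) for the preclinical
characterization of nano-enabled health products (NHPs) — medicinal
products and medical devices that contain a nanomaterial.

## The problem

Bringing an NHP towards the clinic requires physicochemical and
immunotoxicological characterization, but which assays apply — and in which
order they are worth running — depends on what is already known about the
material: a tracking analysis needs particles in a measurable size window,
light-scattering techniques break down on highly polydisperse samples,
chromatographic fractionation with UV-VIS/RI detection is unsuitable for
metal-oxide particles, and an in chemico skin-sensitisation assay only makes
sense for dermal products without systemic exposure. `nanoits` encodes this
expert knowledge declaratively and computes, for each category endpoint of
the nanomaterial, a prioritized and fully explained list of candidate
assays. It is aimed at NHP developers and safety assessors who want a
transparent, reproducible account of *why* each assay was proposed or
ruled out.

## How it works

**Knowledge base.** A YAML file declares modules (physicochemical,
immunotoxicity, …), category endpoints (particle size diameter, surface
charge ζ, polydispersity, refractive index, formulation, …), and for each
quantitative endpoint a partition of its domain into qualitative classes —
e.g. particle size: small (< 30 nm), mid-low ([30, 60) nm), mid-high
([60, 200) nm), big (≥ 200 nm); surface charge: negative (ζ < −10 mV),
neutral (−10 mV ≤ ζ ≤ 10 mV), positive (ζ > 10 mV). Assays carry four
ordinal characteristics (duration, cost, resolution, expertise; each
low/medium/high, scored 1/2/3) and an applicability rule: an AND/OR/NOT
tree over endpoint–class atoms.

**Three-valued evaluation.** A dossier is usually incomplete, so rules are
evaluated in Kleene's strong three-valued logic (TRUE/FALSE/UNKNOWN, with
AND = min and OR = max over FALSE < UNKNOWN < TRUE). An assay is excluded
only when its rule is *known* false — missing knowledge never removes an
option. A brute-force oracle that enumerates all completions of the unknown
endpoints backs the evaluator in the test suite.

**Prioritization.** Applicable assays are ranked by

```
priority = duration + cost + (3 − resolution) + expertise      (range 3–11)
```

lower being better, presented in two resolution groups (low vs
medium–high), ties broken by assay id.

**Iteration.** The ITS loop is: run a step, perform the best assay, record
its results, derive the characterization class, re-run. The engine is
stateless and deterministic; the decision when enough is known is the
user's.

## Worked example

The packaged knowledge base ships with five case-study dossiers:
dextran-coated iron-oxide nanoparticles (`ionp`, a medical device),
a PEGylated liposome (`liposome`), an iron-carbohydrate product
(`iron_carbohydrate`), a poly(alkylcyanoacrylate) product (`paca`), and a
knowledge-free `empty` dossier.

```python
from nanoits import default_kb, dossier_fixture, its_step

kb = default_kb()
entry = its_step(kb, dossier_fixture("ionp")).lookup("nm", "particle_size_lower")
print([r.assay_id for r in entry.group("low")])   # ['nta']
```

The same from the command line (writing the fixture to `ionp.yaml` first):

```
$ nanoits its --kb default_kb.yaml --dossier ionp.yaml --format text
Intelligent testing strategy report

[nm] physicochemical / particle_size_lower
low resolution assays:
  1. nta priority=8 [duration 2 + cost 2 + (3-resolution) 2 + expertise 2]
excluded:
  af4_uv_vis_ri: required NOT (particle_classification (Particle classification) = metal_oxide)
  cf3_uv_vis_ri: required NOT (particle_classification (Particle classification) = metal_oxide)
  dls: required NOT (polydispersity (Polydispersity index (PDI)) = high)
  sec_uv_vis_ri: required NOT (particle_classification (Particle classification) = metal_oxide)
  sls: failed: particle_size_lower (Particle size diameter (lower bound)) within [60, 10000] nm
...
```

Reading: for the iron-oxide device, nanoparticle tracking analysis is the
only remaining low-resolution sizing assay (priority 8 = 2+2+2+2 over its
four characteristics). The fractionation techniques are excluded because
the particle is classified as a metal oxide, dynamic light scattering
because polydispersity is high, and static light scattering because the
asserted size class ([30, 60) nm) lies outside its working range. With the
`empty` dossier the same command lists all six sizing assays, led by DLS
(priority 5) and SLS (priority 6), and reports "No exclusions".

Other subcommands: `nanoits kb validate <kb.yaml>` (exit 0/1/2),
`nanoits record` (append a measurement, atomic file rewrite),
`nanoits derive` (measurements → characterization class), and
`nanoits report` (Markdown/JSON decision-trace report).

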