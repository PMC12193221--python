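# hrmid

In-silico PCR-HRM species identification for necrophilous flies.

Forensic entomologists estimate the postmortem interval from the insects
colonising remains, which requires identifying fly species — including
larvae and degraded, long-stored specimens that defeat both morphological
keys and long-read sequencing. PCR-HRM (high-resolution melting) sidesteps
both: a short mitochondrial barcode (here a 97 bp COXII fragment, or a
278 bp COXI fragment) is amplified with saturating dye, and the amplicon's
melting temperature — read as the peak of the −dF/dT melt curve — is
compared against co-amplified reference species. Peaks closer than
**0.15 °C** imply the same species; separations of 0.15 °C or more imply
distinct sequences. The instrument resolves ±0.02 °C, so a single-base
difference is detectable.

`hrmid` implements the desk side of that workflow end to end:

* **Panels & fixtures** — reference Tm panels (TSV/JSON round-trip at
  0.01 °C), aligned-FASTA IO, and a seeded synthetic barcode generator
  with conserved flanks and a divergent core (`hrmid.io`, `hrmid.synth`,
  `hrmid.panels`).
* **Conservation profiling** — per-column identity/gap profiles of aligned
  panels and conserved/variable block calling (`hrmid.align`).
* **Primer design** — 20 ± 2 nt / 40–60% GC / ≤300 bp screening with
  hairpin and self-dimer run rules, pair enumeration over conserved
  flanks, and mismatch-tolerant in-silico PCR with an exact 3′ seed
  (`hrmid.primers`).
* **Thermodynamics** — unified nearest-neighbor ΔH/ΔS sums with entropic
  salt correction and two-state Tm (`hrmid.thermo`). Predictions are used
  for ranks and ΔTm only; measured panels are data, not targets.
* **Melt curves** — logistic-mixture simulation over the 65→90 °C ramp,
  Savitzky–Golay derivative curves, and a two-stage peak caller (count on
  a smoothed copy, then joint sech² fitting) that recovers planted Tms to
  ±0.02 °C under realistic noise (`hrmid.meltcurve`).
* **Classification** — `TmPanelClassifier`, a scikit-learn-style estimator
  applying the 0.15 °C rule with explicit ambiguity, multi-peak signature
  handling, a panel discriminability audit, replicate-drift QC and
  cross-batch warnings (`hrmid.classify`).
* **Bench planning** — the 20 µL reaction table, the ≥10 ng
  template-quantity rule, and the thermocycler program (`hrmid.protocol`).

## Worked example

Classify a larval sample whose melt peak came out at 77.50 °C against the
five-species flesh-fly reference panel it was co-amplified with:

```python
>>> from hrmid import classify, panels
>>> result = classify([77.50], panels.cox2_larva_panel())
>>> result.to_dict()
{'query_id': 'query', 'status': 'match', 'assigned_species': 'P. dux',
 'delta_tm': 0.1, 'candidates': [['P. dux', 0.1]]}
```

Only *P. dux* (77.40 °C) lies within 0.15 °C of the query, so the larva is
called *P. dux* at a ΔTm of 0.10 °C. Ambiguity is never hidden — a fresh
adult at 76.73 °C sits exactly on *B. peregrina* but only 0.03 °C from
*H. ligurriens*, and both are reported:

```python
>>> classify([76.73], panels.cox2_panel()).to_dict()
{'query_id': 'query', 'status': 'ambiguous', 'assigned_species': None,
 'delta_tm': 0.0, 'candidates': [['B. peregrina', 0.0], ['H. ligurriens', 0.03]]}
```

The discriminability audit makes the same point panel-wide: five of the 45
species pairs in the ten-species COXII panel sit within 0.15 °C of each
other:

```python
>>> from hrmid import pairwise_discriminability
>>> pairwise_discriminability(panels.cox2_panel())
[('A. rufifacies', 'P. misera'), ('A. rufifacies', 'P. ruficornis'),
 ('B. peregrina', 'H. ligurriens'), ('C. megacephala', 'P. misera'),
 ('P. dux', 'P. sericea')]
```

Replicate QC across two extraction runs of the five flesh-fly species shows
a drift of 0.02–0.10 °C, every species shifting upward — which is why
unknowns should be co-amplified with their references:

```python
>>> from hrmid import replicate_error
>>> rep = replicate_error(panels.cox2_panel(), panels.cox2_repeat_panel())
>>> rep.per_species, rep.min_error, rep.max_error, rep.n_upward
({'B. peregrina': 0.1, 'P. dux': 0.1, 'P. misera': 0.03,
  'P. ruficornis': 0.08, 'P. sericea': 0.02}, 0.02, 0.1, 5)
```

Bench planning — the weakest extract measured only 3.83 ng/µL, so the
reaction loads 3 µL of template and 4 µL of water to reach the 10 ng
minimum inside the 7 µL budget:

```python
>>> from hrmid import template_volume
>>> template_volume(3.83)
(3, 4)
```

A thin CLI wraps the same functions:

```bash
hrmid classify --query 77.50 --panel larva_panel.tsv
hrmid melt --components 74.75:1,77.65:1,80.32:1 -o curve.csv --peaks
hrmid design --alignment aln.fasta --product-max 300
hrmid mix --conc 3.83 -n 8
```

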