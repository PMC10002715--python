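# JSON model dialect

The canonical on-disk format for taxon models. SBML Level 3 + FBC is
supported for interoperability (see `mcmm.io`), but toy and synthetic models
are easiest to read and hand-edit as JSON.

```json
{
  "taxon_id": "butyrogen",
  "rank": "genus",
  "metabolites": [
    {
      "id": "glucose",
      "name": "D-glucose",
      "compartment": "e",
      "formula": "C6H12O6",
      "annotations": {"host_absorbable": true}
    }
  ],
  "reactions": [
    {
      "id": "EX_glucose",
      "stoichiometry": {"glucose": -1.0},
      "lower_bound": -10.0,
      "upper_bound": 1000.0,
      "exchange": true,
      "biomass": false
    }
  ]
}
```

Rules:

- `taxon_id` nonempty; `rank` is `genus` or `species` (default `genus`).
- Metabolite `id`s are unique; `formula` is optional and, when present, must
  tokenize as element symbols (one uppercase letter optionally followed by
  one lowercase letter) with positive integer counts.
- `annotations` carries the boolean medium-construction flags
  `host_absorbable`, `host_supplied`, `residual_fiber`,
  `carbon_source_override`.
- Reaction stoichiometry maps metabolite id to a signed coefficient
  (negative = consumed) and must be nonempty; `lower_bound <= upper_bound`,
  units mmol/gDW/h.
- Exactly one reaction has `"biomass": true`; its flux is the growth rate
  in 1/h.
- An exchange reaction touches exactly one metabolite with coefficient -1;
  **positive flux is secretion**, uptake is negative flux bounded below by
  the medium. SBML files written with the opposite convention (exchange as a
  product) are normalized on load.
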