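# ribiscreen

Analysis pipeline for genome-wide, plate-based duplex qPCR reporter
screens, written for the design in which a ribosome-biogenesis reporter
(*NSR1*, FAM channel) is measured against a housekeeping gene (*PEX6* or
*NTF2*, JOE channel) across a yeast knock-out library under osmotic
stress, mock treatment, and rapamycin.

It is aimed at labs running arrayed expression screens who need the whole
statistical chain, not just one step:

1. **Plate ingest & filtering** — typed well records; wells whose Ct
   crossed threshold after >28 cycles (or never) are discarded.
2. **Mixture normalization** — per plate, the F–J value (Ct_FAM − Ct_JOE)
   is fitted with a two-component 1-D Gaussian mixture (EM, in-repo); the
   mean of the majority (defect-free) population is subtracted and the
   sign flipped, cancelling the 0.3–0.6-cycle run offsets. Hit-enriched
   re-array plates are centered on center-peak control wells instead.
3. **Error model & hit calling** — replicate screens give the null
   N(0, 0.3) for normalized log2 ratios; at the log2 > 1.0 cutoff a null
   strain passes with probability < 0.1% (Z ≈ 3.3). Hits are re-arrayed,
   selected at log2 > 1.3, and confirmed at log2 > 1.0 against a second
   housekeeping gene.
4. **Epistasis classification** — confirmed hits are re-run under mock
   stress (constitutive if log2 > 1.0) and rapamycin (downstream of TORC1
   if log2 ≥ 1.0, otherwise upstream/parallel).
5. **Network connectivity** — induced-edge count of the confirmed set in
   an evidence-typed interaction graph, tested against 10,000 random
   same-sized gene sets with an add-one empirical p-value
   (p = (exceedances + 1)/(permutations + 1)); hub pruning, component
   statistics, hypergeometric set enrichment, GraphML/SIF export.

A calibrated synthetic-data generator (`ribiscreen.synthetic_data`)
produces screens and interaction graphs with known ground truth, so every
stage is testable without instrument data. See `docs/methods.md` for the
model, all defaults, and what the generator does and does not emulate.

## Worked example

```sh
ribiscreen all --out-dir study_out --n-strains 960 --n-perm 2000 --seed 3
```

runs a full synthetic study (simulate → filter → normalize → call →
confirm → classify → permutation test) and prints the study report. With
the command above it prints, among other fields:

```json
{
  "replicate_stats": {"pearson_r": 0.929, "mean_abs_diff": 0.284, "n_pairs": 533},
  "null_model": {"mean": 0.0, "sd": 0.3, "source": "replicate_derived"},
  "n_primary_hits": 91,
  "n_selected": 85,
  "n_confirmed": 80,
  "class_counts": {"downstream_TORC1": 12, "upstream_or_parallel": 60,
                   "constitutive": 1, "not_hit": 5, "unclassified": 7},
  "permutation": {"observed_edges": 33, "null_mean": 16.3,
                  "null_max": 31, "empirical_p": 0.0005}
}
```

Reading: the two replicate runs of the first six plates agree with Pearson
r = 0.93 and a mean absolute difference of 0.28 log2 units, giving the
null model N(0, 0.3). Of 927 screened strains, 91 exceed log2 = 1.0, 85
pass the 1.3 re-array cutoff, and 80 confirm against the second
housekeeping gene; the rapamycin subscreen places 12 of them downstream of
TORC1 and the mock subscreen flags one constitutive strain. The 80
confirmed genes share 33 interaction edges where random 80-gene sets
average 16.3 and never reach 33 in 2,000 draws, so the connectivity
enrichment gets the minimum reportable p ≈ 5×10⁻⁴.

Each stage is also available as its own subcommand (`simulate`, `filter`,
`normalize`, `screen`, `confirm`, `classify`, `network`, `report`) reading
and writing file artifacts in `--out-dir`, and as plain library functions
(`ribiscreen.normalize_plate`, `ribiscreen.permutation_test`, ...).

Real data enter through the documented formats: wells as CSV
(`plate_id, well, strain_id, condition, role, ct_fam, ct_joe`) and
interaction edges as 3-column TSV (`gene_a, gene_b, evidence_class`, with
a bundled mapping from BioGRID experimental-system names to the three
evidence classes).

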