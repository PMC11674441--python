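# neovax

A tested, reusable implementation of the computational pipeline behind
personalised neoantigen peptide vaccines, aimed at cancer immunoinformatics
groups who want each stage as a library function rather than a black box:

1. **Somatic SNV calling** from tumour/normal allele-count tables by
   Fisher's exact test with explicit filters — base quality ≥ 15, depth ≥ 10,
   variant depth ≥ 4, tumour VAF ≥ 10 %, normal VAF < 2 %, p < 0.05 on the
   2×2 table [[t_alt, t_ref], [n_alt, n_ref]];
2. **Effect annotation** (minimal codon substitution against supplied
   transcript models) and **mRNA expression confirmation** at mutation sites;
3. **Mutant peptide enumeration**: all 8–11-mers (HLA class I) and
   15–18-mers (HLA class II) covering the changed residue(s);
4. **Vaccine peptide selection**: HLA class II long peptides with predicted
   IC50 < 500 nM (≤ 50 nM = "strong" tier), expressed, and containing — or
   terminally overlapping by ≥ 4 residues — an HLA class I epitope also
   under the gate;
5. **ELISpot immunomonitoring**: per-well activity
   `Σ(intensity × size) / 1000`, duplicate aggregation, and the ≥ 1.5×
   fold-change positivity rule against a per-sample control;
6. **TCR repertoire clonality**: inverse Simpson (`1/Σp²`) and Shannon
   (`−Σp·ln p`) diversity, the > 0.5 % expanded-clonotype display set, and
   pre/post-vaccine comparison (emergent/contracted clonotypes, clonality).

Every input can be simulated with planted ground truth
(`neovax.synthetic_data`), so the whole pipeline runs and is tested without
any patient data. The published per-patient selection table ships as a
package fixture (`neovax.epitope_selection.load_table3`) and is re-run
through the selection logic in the tests. See `docs/methods.md` for models,
defaults and limitations.

## Worked example

One command generates a synthetic patient (tumour/normal counts with planted
somatic sites, transcript models, RNA support, a hash-based but plantable
affinity table, an ELISpot plate with planted positives, and pre/post TCR
tables) and runs everything:

```bash
neovax demo --seed 7 --out demo/
```

Top of `demo/selection.tsv` (columns abridged):

```
Gene      Exp.Level  AA_Change  ClassII_Peptide     ClassII_Affinity_nM  ClassI_Peptide  ClassI_Affinity_nM  Relationship  Tier    Rank
GENE0001  34         V406L      SIHFFAPARLGRMEL     2.0                  ARLGRMEL        5.0                 contained:7   strong  1
GENE0022  39         V397A      YEHYLAMTPDLCHRKG    2.6804               HYLAMTPDLCH     7.66381             contained:2   strong  2
GENE0021  8          S50C       YGWISGCHYLGVRHSEAT  4.24896              CHYLGVRHSEA     15.725              contained:6   strong  3
```

Reading row 1: the missense variant V406L in GENE0001 is expressed (34
mutant RNA reads); its best class II long peptide binds DRB1\*04:05 at a
predicted 2 nM and contains (at offset 7) an 8-mer that binds HLA-A\*02:01
at 5 nM — exactly the planted strong nested pair, recovered at rank 1.
The run also reports the ELISpot calls (`positive: 3` of 10 conditions —
the three planted ones) and the TCR comparison (inverse Simpson falls from
143.7 to 134.4 as the ten planted clonal expansions emerge above 0.5 %).

Per-stage commands (`neovax call / enumerate / select / elispot / tcr`) run
each step on files, and `neovax run --config run.yaml` drives the whole
pipeline from a flat YAML config; library functions mirror every command.

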