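# aavbench

Quantitative pipeline for **multiplexed barcoded-AAV capsid evaluation in ex
situ normothermically perfused human livers**. In such studies a pool of AAV
capsid variants — each packaging the same transgene tagged with a unique
44-mer DNA barcode — is injected into a machine-perfused liver graft, and the
fate of every variant is tracked simultaneously: clearance from the
perfusate, uptake into hepatocytes (barcodes in tissue DNA), and functional
transduction (barcodes in cDNA). `aavbench` implements the full analysis
stack for this design, for vectorology groups running barcode-seq capsid
comparisons and for anyone re-analysing such data.

## What it computes

- **Barcode demultiplexing** (`aavbench.demux`): paired 2×150 amplicon reads
  are merged on their best suffix/prefix overlap (quality-weighted consensus),
  filtered to the expected amplicon length, and assigned to variants by
  locating the barcode window between fixed anchor primers and taking the
  unique nearest barcode under Hamming distance
  (radius `max_hamming`, default 3). Read accounting is exact:
  assigned + ambiguous + unmatched + unmerged + length-filtered = input pairs.
- **Composition profiles** (`aavbench.composition`): count fractions
  f_i, enrichment against the pre-injection mix r_i = f_i/m_i, and
  renormalized percentages p_i = 100·r_i/Σ_j r_j — the quantity plotted in
  transduction heatmaps. Also cDNA%/DNA% expression-efficiency ratios,
  replicate-based barcode-bias screening, and average-linkage hierarchical
  clustering of profiles (Euclidean, Newick export).
- **Kinetics and dosimetry** (`aavbench.kinetics`): ddPCR Poisson
  quantification λ = −ln(1 − n₊/n) with concentration λ/v·dilution;
  per-variant perfusate curves C_i(t) = C_tot(t)·f_i(t) and
  percent-of-initial q_i(t); persistence classes (≥10% persistent,
  0.1–10% intermediate, 0.01–0.1% fast-cleared, <0.01%
  neutralized-cleared); log-linear clearance-rate fits
  C(t) = C₀((1−π)e^(−kt) + π); vector copy number per haploid cell; and dose
  arithmetic (vg per kg liver/body, per capsid, initial perfusate vg/mL).
- **Serology** (`aavbench.serology`): ELISA reactivity (foreground/background
  ratio strictly > 2.0), end titers over a 1:25/1:50/1:100 dilution series,
  NAb 50%-inhibition titers, and a tie-aware Spearman rank correlation with
  exact permutation p-values at small n.
- **Viability** (`aavbench.viability`): lactate ≤ 2.5 mmol/L plus ≥ 2 of
  bile production, pH ≥ 7.30, glucose metabolism, arterial flow ≥ 150 mL/min,
  portal flow ≥ 500 mL/min, homogeneous perfusion.
- **Synthetic data** (`aavbench.simulate`): seed-deterministic generators for
  every input — barcode libraries, paired FASTQ with substitution/indel
  errors, perfusate decay with reactivity-coupled rates, tiered ELISA
  plates, ddPCR droplets — with ground truth recorded for every read.
- **Workbench** (`aavbench.workbench`): YAML manifest → full study run with
  per-figure TSV outputs and a JSON run log.

## Worked example

Simulate a 14-variant equimolar run, demultiplex it, and compute the dose
report for a 2.57×10¹² vg injection into a 0.67 kg graft:

```bash
aavbench simulate reads --out-prefix demo --n-reads 20000 --seed 7
aavbench demux --r1 demo_R1.fastq --r2 demo_R2.fastq \
    --library demo_library.tsv --config demo_config.yaml \
    --out demo --sample-id demo
```

```
sample_id        demo
total_input_pairs        20000
n_assigned       19903
n_ambiguous      0
n_unmatched      97
n_unmerged       0
n_length_filtered        0
```

At the default 0.3% per-base error rate, 99.5% of pairs are assigned
(the 97 unmatched reads carry more than 3 substitutions inside the barcode
or a broken anchor); per-variant counts (`demo.counts.tsv`) land within
multinomial sampling error of the 20000/14 ≈ 1429 expectation, e.g.
`AAV-BC01 1389`, `AAV-BC02 1426`, `AAV-BC05 1463`.

```bash
echo '{"total_vg": 2.57e12, "liver_mass": 2.19, "graft_mass": 0.67,
       "n_variants": 14, "perfusate_volume": 2.0}' > dose.json
aavbench dose --context dose.json
```

```json
{
  "initial_perfusate_conc_vg_per_ml": 1285000000.0,
  "per_kg_liver": 3835820895522.3877,
  "per_variant_per_kg_liver": 273987206823.02768,
  "perfusate_volume_l": 2.0,
  "total_vg": 2570000000000.0
}
```

That is 3.84×10¹² vg per kg of liver, 2.74×10¹¹ vg/kg per capsid, and an
initial perfusate concentration of 1.29×10⁹ vg/mL in the nominal 2.0 L
circuit.

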