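# cladeprimer

In-silico evaluation of clade-specific PCR and qPCR primers, built around the
marker-gene workflow used to detect and quantify the nitrate-driven anaerobic
methanotroph *'Candidatus* Methanoperedens nitroreducens' (ANME-2d / GOM Arc I)
via its *mcrA* and 16S rRNA genes. It is aimed at molecular microbial
ecologists who design or vet clade-specific primers against labeled reference
databases before going to the bench.

## What it computes

* **IUPAC-aware primer matching.** A primer base matches a template base iff
  their IUPAC sets intersect, so degeneracy in the primer is never counted as
  a mismatch. Substitutions only; no indels. `scan_binding_sites` slides a
  primer over both strand orientations of an ungapped template and reports
  every footprint with ≤ *m* mismatches (1-based inclusive + strand
  coordinates, mismatch positions 5′→3′ of the primer).
* **Primer properties.** Length, degeneracy (product of per-position set
  sizes), expected GC% over the uniform mixture of encoded oligos, and the
  Wallace-rule Tm 2(A+T) + 4(G+C) (pluggable — other Tm models can be passed
  in).
* **Amplicon prediction.** `predict_amplicons` pairs forward/reverse hits in
  amplifiable orientation and carries two product sizes: the inclusive
  physical length rev_end − fwd_start + 1, and the reported size
  rev_end − fwd_start used by the published primer tables this package
  mirrors (186 bp for McrA159F/McrA345R, 1191 bp for McrA169F/McrA1360R,
  212 bp for AAA641F/AAA834R).
* **Coverage vs. specificity.** For allowed mismatches m ∈ {0, 1, 2, 3+}:
  intra-group coverage = 100 × |in-group sequences with ≥ 1 site at ≤ m| /
  |in-group|, and the count of out-group (non-target) sequences hit at the
  same allowance — the standard probe-match style table, per primer or per
  pair.
* **Amplicon phylogenetics.** Pairwise identity (gap and ambiguity columns
  excluded), Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3), and a
  deterministic Saitou–Nei neighbor-joining implementation with Newick
  export (scikit-bio trees).
* **qPCR quantification.** OLS standard curve Ct = slope·log₁₀(copies) +
  intercept, efficiency E = 10^(−1/slope) − 1, inversion to copies per
  reaction, scaling to copies per gram wet weight, and replicate aggregation
  (mean, SD, median, type-7 quartiles) with explicit non-detect ("ND")
  handling.
* **Synthetic ground truth.** `generate_reference_db` builds labeled
  databases with planted binding sites at controlled per-sequence mismatch
  counts; `evolve_alignment` simulates sequences down a tree under the JC
  model; `simulate_qpcr_plate` produces noisy plates from a known curve.
  Every generator emits a manifest that the real pipeline is checked
  against.

## Worked example

```python
from cladeprimer import QPCR_PAIR, SyntheticConfig, generate_reference_db
from cladeprimer import coverage_table, predict_amplicons, primer_properties

fwd, rev = QPCR_PAIR                       # McrA159F / McrA345R
for p in (fwd, rev):
    props = primer_properties(p)
    print(f"{p.name}: {props.length} nt, GC {props.gc_percent:.1f}%, "
          f"degeneracy {props.degeneracy}")

config = SyntheticConfig(seed=1, in_group_size=10, out_group_size=20,
                         mismatch_schedule=((0.7, 0), (0.3, 2)))
db, truth = generate_reference_db(config)

(pred,) = predict_amplicons(fwd, rev, db.records[0], max_mismatches=0)
print(f"product: {pred.product_size_reported} bp "
      f"(inclusive {pred.product_size_inclusive} bp), "
      f"footprints {pred.fwd_hit.start}-{pred.fwd_hit.end} / "
      f"{pred.rev_hit.start}-{pred.rev_hit.end}")

print(coverage_table(fwd, db).to_frame().to_string(index=False))
```

prints

```
McrA159F: 22 nt, GC 54.5%, degeneracy 1
McrA345R: 23 nt, GC 56.5%, degeneracy 1
product: 186 bp (inclusive 187 bp), footprints 159-180 / 323-345
mismatches  intra_group_percent  out_group_hits
         0                 70.0               0
         1                 70.0               0
         2                100.0               0
        3+                100.0               0
```

The 186-bp reported product is the published size of the McrA159F/McrA345R
qPCR amplicon; the coverage ladder (70% of the in-group at 0 mismatches,
100% from 2 mismatches on, zero non-target hits) is exactly what the
generator planted, confirming the scan/coverage machinery end to end.

The same operations are available from the shell via the `cladeprimer` CLI
(`props`, `mismatch`, `coverage`, `pcr`, `phylo`, `quant`, `simulate`); all
outputs are TSV/FASTA/Newick with a `#` parameter header, and identical
seeds give byte-identical artifacts.

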