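# bestop

Design and quantification tools for cytidine base-editing (BE3-style)
gene knockout by premature stop codon.

A cytidine base editor converts C:G base pairs to T:A inside a
deamination window of its 20-nt protospacer (positions numbered C1..C20
from the PAM-distal end, PAM = NGG). Four sense-strand codons can be
turned into stop codons this way:

```
CAA -> TAA,  CAG -> TAG,  CGA -> TGA      (edit the sense-strand C, + protospacer)
TGG -> TAG | TGA | TAA                    (edit the antisense C(s), - protospacer)
```

`bestop` implements both halves of the computational workflow around
such an editor:

* **Design** (`bestop.design`): scan coding sequences for every
  (in-frame target codon, NGG protospacer) pair whose required edits
  fall inside a configurable editing window — default C1–C13, canonical
  in-vitro C4–C8 — and summarize targetability per gene (site counts,
  medians, positional deciles).
* **Quantification** (`bestop.quant`): from barcoded amplicon deep-
  sequencing reads, run quality trimming (leading/trailing plus sliding
  mean-quality window), exact barcode-pair demultiplexing, global
  affine-gap alignment to the amplicon reference, per-read
  classification by C→T conversion inside the 20-bp target, per-gRNA
  efficiency `n_edited / n_clean`, per-position substitution matrices,
  editing-window probabilities across a gRNA panel (`#gRNAs edited at
  Cn / #gRNAs designed with Cn`), multiplex substitution counting, and
  indel frequency from alignment gaps.
* **Simulation** (`bestop.simulate`): synthetic CDS sets with planted
  knockout sites and synthetic barcoded amplicon reads with known
  per-position editing probabilities, indel rates, and sequencing
  error, for validating every stage against ground truth.

Intended users are people designing stop-codon knockout screens with a
cytidine base editor, and people quantifying editing outcomes from
targeted amplicon sequencing.

## Worked example

```python
from bestop import CdsRecord, EditWindow, scan_cds, summarize_genome, clone_efficiency

seq = list("A" * 36)
seq[0:3] = "ATG"; seq[12:15] = "CAG"   # in-frame CAG at codon 5
seq[29] = "G"; seq[30] = "G"           # completes an NGG PAM
cds = CdsRecord.from_bases("demo", "".join(seq))

(site,) = scan_cds(cds, EditWindow(1, 13))
print(site.codon, "->", site.resulting_stop, "at codon", site.codon_index_1based,
      "editing protospacer position", site.edited_positions)
# CAG -> TAG at codon 5 editing protospacer position (5,)

summary = summarize_genome([site], ["demo", "other_gene"])
print(f"{summary.percent_targetable:.1f}% of genes targetable")
# 50.0% of genes targetable

print(clone_efficiency(7, 12))   # 58.3 : percent of mutant clones, 1 d.p.
```

The scan found exactly one knockout site: the planted in-frame CAG whose
editable C sits at protospacer position 5 of the only NGG protospacer,
and a C→T edit there creates the TAG stop codon. With one of two genes
carrying a site, half the gene set is targetable.

A full CLI mirrors the library (`bestop scan`, `bestop quant`,
`bestop multiplex`, `bestop simulate cds|reads`); every run writes TSV
tables, figure twins of each plot, and a JSON manifest with content
checksums.

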