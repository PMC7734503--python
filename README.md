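# zotukit

A toolkit for integrating public fungal ITS metabarcoding data across
studies. It covers the full path from publication text to biogeographic
queries:

* **Accession mining** (`zotukit.accessions`) — find sequence-archive
  identifiers (SRA `SRA/SRP/SRS/SRX/SRR`, BioProject `PRJNA/PRJEB`, ENA
  `ERP/ERS`) in plain-text publications, with word-boundary rules that
  reject in-word and digit-less look-alikes; map publications to studies
  with structured cross-references taking precedence over full-text
  mining.
* **Metadata curation** (`zotukit.curation`) — standardise heterogeneous
  sample metadata: dates to ISO 8601, coordinates (decimal, hemisphere
  and DMS dialects) to decimal degrees, countries to a bundled gazetteer
  (canonical name, GeoNames id, continent, centroid, bounding box), and
  habitat descriptions to ENVO terms by longest dictionary match.
  Samples without coordinates get the country centroid
  (`CENTROID_FALLBACK`); reported coordinates outside the country's
  bounding box are repaired to the centroid (`CORRECTED`). Every curated
  field keeps its original value as provenance, so curation is
  losslessly invertible.
* **Amplicon pipeline** (`zotukit.pipeline`) — FASTQ (Sanger Phred+33)
  to zero-radius OTUs: IUPAC-aware primer trimming, paired-end merging
  (best-offset overlap, >= 60 bp and >= 90% identity by default),
  expected-error filtering (EE = sum of 10^(-Q/10), maxEE inclusive),
  exact dereplication, greedy abundance-ordered denoising with skew
  threshold beta(d) = 1/2^(alpha*d + 1) (alpha = 2, min_size = 8 by
  default), and a taxonomy filter that aligns each ZOTU against a
  lineage-bearing reference FASTA and keeps hits >= 70% identity with a
  fungal best hit. Single-read platforms (454, Ion Torrent) skip the
  merge. Every run emits a per-stage count report obeying an exact
  read-conservation law, plus a process record capturing all parameters.
* **Reference store** (`zotukit.store`) — an embedded (SQLite) store of
  deduplicated ZOTU reference sequences with a `contains` provenance
  relation (which sample/run each ZOTU was observed in), process
  records, taxon assignments and the study/experiment/sample/run
  hierarchy. Incremental updates insert unseen sequences and only add
  `contains` rows for known ones; replays are idempotent; every
  experiment must name a sample.
* **Biogeographic queries** (`zotukit.queries`) — presence-based
  phylum-by-continent counts, shared/pairwise ZOTU overlap between
  continents, and per-sample taxon counts within a latitude band
  (tropics by default, ±23.43651°), with GeoJSON point output.
* **Fixtures** (`zotukit.fixtures`) — seeded generators for synthetic
  FASTQ libraries (planted ZOTUs with known error positions), reference
  FASTAs (fungal lineages plus verified <70%-identity decoys),
  publication corpora with planted accessions, and raw metadata tables
  covering every recognised dialect — each with a ground-truth table.

## CLI

```sh
zotukit mine --text publication.txt --doi 10.x/y --out matches.csv
zotukit curate --samples samples.csv --out curated.csv
zotukit process --fwd R1.fastq --rev R2.fastq \
    --fwd-primer GTGARTCATCGAATCTTTG --rev-primer TCCTCCGCTTATTGATATGC \
    --marker ITS2 --platform ILLUMINA_MISEQ --ref unite.fasta --out run1/
zotukit update --store store.db --zotus run1/zotus.fasta --srs SRS1 --srr SRR1
zotukit export --store store.db --out export/
zotukit query phylum-by-continent --store store.db
zotukit query shared --store store.db
zotukit query band --store store.db --rank family --name Russulaceae
zotukit simulate library --seed 1 --out sim/
```

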