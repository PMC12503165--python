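# ai2net

Genome mining of quorum-sensing (QS) capacity in microbial communities and
assembly of the autoinducer-2 (AI-2) interspecies communication network.

## The scientific problem

Gut bacteria coordinate behaviour through diffusible QS signals. Most
signal classes (acyl-homoserine lactones, autoinducing peptides, DSFs, ...)
are species-specific, but AI-2 — the cyclised derivatives of
4,5-dihydroxy-2,3-pentanedione made by the synthase LuxS — is produced and
sensed across Gram-positive and Gram-negative species, which makes it the
prime candidate for genuine interspecies communication. Whether a community
can actually talk via AI-2 depends on who carries the synthase and who
carries a receptor. Four receptor types are recognisable from an annotated
genome:

* **LuxP** — the periplasmic borate-form receptor of *Vibrio* spp.
  (annotation keyword search);
* **LsrB** — the periplasmic non-borate receptor, functional only as part
  of the `lsrACDB` ABC-importer operon with its regulators `lsrK`/`lsrR`
  (keyword search plus an operon-context rule);
* **dCache_1** — transmembrane signal-transduction proteins (PF02743) whose
  extracellular double-Cache domain binds AI-2 when five residues are
  conserved at the positions numbered **R126, W128, Y144, D146, D173** in
  *Pseudomonas aeruginosa* PctA;
* **GAPES1** — YeaJ-like c-di-GMP synthases of *Enterobacteriaceae*
  (PF17155) that bind AI-2 when the residues at YeaJ positions **Y210 and
  D239** are conserved.

`ai2net` implements this screen end to end for annotated genomes:

1. **genomes** — GFF3/GenBank + protein-FASTA ingestion, GTDB taxonomy
   parsing, CheckM-style quality filter (completeness > 90 %,
   contamination < 5 %, strict), genus representative selection;
2. **census** — lexicon-based detection of the synthases for 13 QS signal
   classes (including multi-gene pathways that require a complete gene
   set), per-signal and per-species tabulation;
3. **receptors** — the four receptor routes above: profile-HMM domain
   search (pyhmmer), Kyte–Doolittle transmembrane topology filtering,
   deterministic residue mapping by global alignment (BLOSUM62, gap open
   10 / extend 0.5) with an MSA mode, and per-position conservation
   profiles;
4. **function_typing** — functional modules (MCP, HK, CSP, SP, STK, AC/GC)
   from output-domain architecture;
5. **expression** — TPM from featureCounts-style tables
   (`TPM = (count/kb) / Σ(count/kb) × 10⁶`) and per-state expression flags
   (luxS high at TPM > 0.2, LsrB > 0.1, dCache_1 > 0.01);
6. **network** — per-species QS profiles with roles (producer_only /
   receiver_only / both / none), the bipartite species–signal network, the
   module-resolved network of dual-role species, phyletic tables and a
   consistency-checked summary;
7. **synthdata** — a deterministic generator of synthetic annotated
   communities and count tables with a truth manifest, so the whole
   pipeline is testable offline.

## Worked example

```python
from ai2net.synthdata import default_plan, generate_community
from ai2net.pipeline import run_pipeline

genomes, truth = generate_community(default_plan(seed=1))
result = run_pipeline(genomes)
print(result.summary["role_counts"])
print(result.census.species_per_signal.to_dict())
```

prints

```
{'producer_only': 26, 'receiver_only': 4, 'both': 14, 'none': 16}
{'2-(2-hydroxyphenyl)-thiazole-4-carbaldehyde': 1, 'AHLs': 1, 'AI-2': 40,
 'AIPs': 5, 'CAI-1': 1, 'DPO': 1, 'DSFs': 1, 'HAQs': 1,
 'dialkylresorcinols': 1, 'indole': 4}
```

i.e. of the 60 synthetic species, 40 carry the AI-2 synthase gene, 18 carry
at least one receptor, and 14 can both produce and sense the signal — the
dual-role species that form the core of the communication network. The same
run is available from the shell:

```bash
ai2net synth --out community/ --seed 1
ai2net run --genomes community/ --out results/
```

which writes call tables (TSV), both networks (GraphML), the phyletic
distribution table and a JSON summary whose identity checks
(`both + receiver_only = receptor species`,
`both + producer_only = synthase species`) are verified on every run.

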