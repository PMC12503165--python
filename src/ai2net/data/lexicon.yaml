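# Versioned synthase lexicon for the 13 quorum-sensing signal classes.
#
# Each signal is detected semantically from Prokka-style annotations:
#   gene_names       - exact, case-insensitive match on the gene name
#   product_keywords - case-insensitive whole-word match on the product string
#                      (a trailing qualifier blacklist rejects e.g.
#                      "tryptophanase-like inhibitor")
#   required_gene_sets - alternative gene sets; a call is emitted only when
#                      every member of at least one set occurs in the genome
#
# The AHL entry records synthase gene names only; exact product wordings for
# the individual AHL synthases are not standardised, which limits fidelity of
# keyword-based AHL detection (see docs/methods.md).
version: 1
qualifier_blacklist: [inhibitor, antagonist, pseudogene, fragment]
signals:
  AI-2:
    gene_names: [luxS]
    product_keywords: ["S-ribosylhomocysteine lyase"]
  AHLs:
    gene_names: [
      lasI, traI, cviI, luxI, luxM, esaI, phzI, yenI, ainS, ahyI, bafI,
      carI, cepI, cinI, raiI, halI, nmuI, ppuI, rhiI, sinI, vanI, vanM,
      vfqI, ypsI, ytbI, afeI, bjaI, expI, rhlI, rpaI, smaI, spsI, yspI,
      asaI, aurI, bpsI, braI, ecbI, edwI, ginI, hanI, mrlI1, mrlI2, mrtI,
      solI, splI, sprI, swrI, tofI, pagI, pcoI, spnI, cerI, avsI, croI,
      eagI, ahlI, psyI, bviI, cciI, abaI, cmrI, msaI, mlaI, eanI, yruI,
      alpI, aqsI, plaI, acuI, nwiI, anoI, filI,
    ]
    product_keywords: ["acyl-homoserine lactone synthase", "autoinducer synthesis protein"]
  AIPs:
    gene_names: [agrB]
    product_keywords: ["accessory gene regulator protein B"]
  indole:
    gene_names: [tnaA]
    product_keywords: [tryptophanase]
  HAQs:
    required_gene_sets:
      - [pqsA, pqsB, pqsC, pqsD]
      - [phnA, phnB]
  CAI-1:
    gene_names: [cqsA]
    product_keywords: ["CAI-1 autoinducer synthase"]
  DPO:
    gene_names: [tdh]
    product_keywords: ["threonine dehydrogenase"]
  2-(2-hydroxyphenyl)-thiazole-4-carbaldehyde:
    required_gene_sets:
      - [ambB, ambC, ambD, ambE]
  3-OH-PAME:
    gene_names: [phcB]
    product_keywords: ["methyltransferase PhcB"]
  3-hydroxypentadecan-4-one:
    gene_names: [lqsA]
    product_keywords: ["autoinducer synthase LqsA"]
  photopyrones:
    gene_names: [ppyS]
    product_keywords: ["photopyrone synthase"]
  DSFs:
    gene_names: [rpfF]
    product_keywords: ["DSF synthase"]
  dialkylresorcinols:
    required_gene_sets:
      - [darA, darB, darC]
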