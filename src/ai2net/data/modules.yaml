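# Functional-module definitions for receptor output-domain architectures.
#
# A receptor protein is assigned the first module in `precedence` whose
# requirement is satisfied by its domain hits:
#   any_of - at least one listed accession present
#   all_of - every listed accession present
# Proteins matching no module are `uncharacterized`; all co-matching modules
# are preserved in the call evidence.  The registry is editable: swap in
# other accessions to change what counts as, e.g., a histidine kinase.
modules:
  MCP:              # methyl-accepting chemotaxis protein
    any_of: [PF00015]
  CSP:              # c-di-GMP synthase and/or phosphodiesterase (GGDEF/EAL)
    any_of: [PF00990, PF00563]
  HK:               # sensor histidine kinase: DHp-family plus ATPase domain
    all_of: [PF00512, PF02518]
  STK:              # serine/threonine kinase
    any_of: [PF00069]
  SP:               # serine phosphatase (PP2C/SpoIIE family)
    any_of: [PF00481]
  AC/GC:            # adenylate/guanylate cyclase
    any_of: [PF00211]
precedence: [MCP, CSP, HK, STK, SP, AC/GC]
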