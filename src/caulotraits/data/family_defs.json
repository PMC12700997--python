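{
  "_comment": "Default gene-family definitions for presence/absence matrices. Each family lists KEGG-ortholog ids (ko) and Caulobacter crescentus CB15 reference locus ids (ref) for the reciprocal-best-hit channel; 'category' groups families for marker-based screens and display. Edit freely: the file is configuration, not code.",
  "flgH": {"ko": ["K02393"], "ref": ["CC_2061"], "category": "flagellum"},
  "fliF": {"ko": ["K02409"], "ref": ["CC_1887"], "category": "flagellum"},
  "fliC": {"ko": ["K02406"], "ref": ["CC_1459"], "category": "flagellum"},
  "flhA": {"ko": ["K02400"], "ref": ["CC_1963"], "category": "flagellum"},
  "flgE": {"ko": ["K02390"], "ref": ["CC_1643"], "category": "flagellum"},
  "motA": {"ko": ["K02556"], "ref": ["CC_0793"], "category": "flagellum"},
  "cheA": {"ko": ["K03407"], "ref": ["CC_0433"], "category": "chemotaxis"},
  "cheY": {"ko": ["K03413"], "ref": ["CC_0437"], "category": "chemotaxis"},
  "mcp":  {"ko": ["K03406"], "ref": ["CC_0428"], "category": "chemotaxis"},
  "pilA": {"ko": ["K02650"], "ref": ["CC_2931"], "category": "t4p"},
  "cpaB": {"ko": ["K02279"], "ref": ["CC_2928"], "category": "t4p"},
  "cpaE": {"ko": ["K02282"], "ref": ["CC_2925"], "category": "t4p"},
  "tadD": {"ko": ["K12512"], "ref": ["CC_2921"], "category": "t4p"},
  "hfsA": {"ko": [], "ref": ["CC_2430"], "category": "holdfast"},
  "hfsB": {"ko": [], "ref": ["CC_2431"], "category": "holdfast"},
  "hfaA": {"ko": [], "ref": ["CC_2628"], "category": "holdfast"},
  "pleD": {"ko": ["K13069"], "ref": ["CC_2462"], "category": "regulator"},
  "dgcB": {"ko": [], "ref": ["CC_1850"], "category": "regulator"},
  "pdeA": {"ko": [], "ref": ["CC_3396"], "category": "regulator"},
  "popA": {"ko": [], "ref": ["CC_1842"], "category": "regulator"},
  "shkA": {"ko": [], "ref": ["CC_0138"], "category": "regulator"},
  "tipF": {"ko": [], "ref": ["CC_0710"], "category": "regulator"},
  "cpdR": {"ko": [], "ref": ["CC_0744"], "category": "regulator"},
  "rcdA": {"ko": [], "ref": ["CC_3295"], "category": "regulator"},
  "ctrA": {"ko": ["K13587"], "ref": ["CC_3035"], "category": "master_regulator"},
  "gcrA": {"ko": [], "ref": ["CC_2245"], "category": "master_regulator"},
  "ccrM": {"ko": ["K13581"], "ref": ["CC_0378"], "category": "master_regulator"},
  "creS": {"ko": ["K18642"], "ref": ["CC_1873"], "category": "morphology"},
  "rsaA": {"ko": ["K12544"], "ref": ["CC_1007"], "category": "s_layer"},
  "rsaD": {"ko": ["K12533"], "ref": ["CC_1009"], "category": "s_layer"},
  "rsaE": {"ko": ["K12534"], "ref": ["CC_1010"], "category": "s_layer"},
  "rsaF": {"ko": ["K12535"], "ref": ["CC_1011"], "category": "s_layer"},
  "pufL": {"ko": ["K08928"], "ref": [], "category": "photosynthesis"},
  "pufM": {"ko": ["K08929"], "ref": [], "category": "photosynthesis"},
  "pufA": {"ko": ["K08926"], "ref": [], "category": "photosynthesis"},
  "pufB": {"ko": ["K08927"], "ref": [], "category": "photosynthesis"},
  "pucA": {"ko": ["K08930"], "ref": [], "category": "photosynthesis"},
  "pucB": {"ko": ["K08939"], "ref": [], "category": "photosynthesis"},
  "bchY": {"ko": ["K11334"], "ref": [], "category": "photosynthesis"},
  "bchL": {"ko": ["K04038"], "ref": [], "category": "photosynthesis"},
  "acsF": {"ko": ["K04035"], "ref": [], "category": "photosynthesis"},
  "crtC": {"ko": ["K09846"], "ref": [], "category": "carotenoid"},
  "crtD": {"ko": ["K09845"], "ref": [], "category": "carotenoid"},
  "crtF": {"ko": ["K09847"], "ref": [], "category": "carotenoid"},
  "cbbL": {"ko": ["K01601"], "ref": [], "category": "cbb"},
  "cbbS": {"ko": ["K01602"], "ref": [], "category": "cbb"},
  "cbbP": {"ko": ["K00855"], "ref": [], "category": "cbb"},
  "cbbX": {"ko": ["K25016"], "ref": [], "category": "cbb"}
}
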