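{
  "comment": "Subsets whose informativeness profile decays more than 5% from its peak before 145.0 Ma, per the published partition tables (mtDNA: bolded rows of the 14-subset scheme; nDNA: bolded rows of the 11-subset scheme).",
  "mtdna": ["subset1", "subset3", "subset4", "subset5", "subset6",
            "subset8", "subset11", "subset12", "subset14"],
  "ndna": ["subset2", "subset5", "subset8", "subset9"],
  "alignment_length": {"mtdna": 10061, "ndna": 7769}
}
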