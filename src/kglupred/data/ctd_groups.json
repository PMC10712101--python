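{
  "hydrophobicity_PRAM900101": ["RKEDQN", "GASTPHY", "CLVIMFW"],
  "hydrophobicity_ARGP820101": ["QSTNGDE", "RAHCKMV", "LYPFIW"],
  "hydrophobicity_ZIMJ680101": ["QNGSWTDERA", "HMCKV", "LPFYI"],
  "hydrophobicity_PONP930101": ["KPDESNQT", "GRHA", "YMFWLCVI"],
  "hydrophobicity_CASG920101": ["KDEQPSRNTG", "AHYMLV", "FIWC"],
  "hydrophobicity_ENGD860101": ["RDKENQHYP", "SGTAW", "CVLIMF"],
  "hydrophobicity_FASG890101": ["KERSQD", "NTPG", "AYHWVMFLIC"],
  "normwaalsvolume": ["GASTPDC", "NVEQIL", "MHKFRYW"],
  "polarity": ["LIFWCMVY", "PATGS", "HQRKNED"],
  "polarizability": ["GASDT", "CPNVEQIL", "KMHFRYW"],
  "charge": ["KR", "ANCQGHILMFPSTWYV", "DE"],
  "secondarystruct": ["EALMQKRH", "VIYCWFT", "GNPSD"],
  "solventaccess": ["ALFCGIVW", "RKQEND", "MPSTHY"]
}
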