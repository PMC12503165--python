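>YeaJ_synthetic synthetic stand-in for S. Typhimurium YeaJ; screened residues Y210 D239; GAPES1 domain 35-300
YQLMVARMALAILLIVLMFIFALIALFILRLNKPEKKDQNKQESTQKNRNTTTAAGGLGV
KLAMIERSVIESSLAIKTKRAFQVSTIDMRIAHKGSISLGPWEFAETKFARTNPSNLLTL
FVSVLRAPSYMEDIVNSDKQCGTFRARNVQLFAITLNIIEFQLRLQTKFWRADLRLANAA
FIPTREIWNIIESEVPGHMHGPDLRKSTLYPNVTDKVNPLRSPDVNDGQQVSRFRTLDDL
ELRYRAIHERQRRSLVVEKDNMASRGRYKRRDTMNELVETVEEKVANNLPLNRPNPTQFA
GEVPLIIAAMLVILLVMLVVVFLIVGASIAFVILVTQETKSFGIFGRRLTTDVSDDPRTI
LSDFEFLTCFLDGYKDRLSGTGVLILPYEAFACHFRFKSMPRQLDQNVCNKQKGLVDKLD
IHRSKSESPDEVARQIDVEVLTKRAGLSVALLWNLVPVAPPETPYFRKKGGKYPGLELVT
LLLTE
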