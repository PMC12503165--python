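>PctA_synthetic synthetic stand-in for P. aeruginosa PctA; screened residues R126 W128 Y144 D146 D173; dCache_1 LBD 40-280
SDQTYAEAVLIIAIIFFMLFVLIIVVFFLVIGIGDSTQMSRVGTRMINDVHEQEPAVLRG
VLETASVVPMDHTSLTPSNQLYDPETTAPGQIDYVLLGQMKHLLDVPMDELGVQRTTAGH
LSNKPRAWDEPMLRTVFGEAAAFYLDAGTISQGQPVSGVRSSIFSTALQKFEDQSNAAVK
RLATYAEDINPSRTLLLADYFLLKPGTETRIRLAICDLGSERELSVHSFNVAGIQGERKQ
EAFVPRHFRYIGAAIEEPQQPARYKDFKKKDEIEIEELGTRLFHNSAIPLLLIFVLFLVV
IFMLVFALFVRSNNEQKKSEQSSQSKKTKYFIVATQINDRTLAAKQKGLYKCHFFSADRR
YDARRCDVLLSADGAHQMTFARRVFRIMVANRAIYNDYGMHILHFWVQGGAHKKIKDTGG
ILLCNSDYIQMKQVGGSDTFFRKAKVLRVL
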