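>GAG_ref
HCGFNLIKVRMSQDCALDSNCPAFACHTYVHNGIIIAIVCHKVMKRWSLCWYYICSAQRE
VSKMGCFYCMPYEPYPIHGLDVDMQIEFQTPRCHRSAVDAVKFWYSDQHEYFVGANLLCL
>AP_ref
QCPLFPFCYKKINCDDRLYNVFLNIGGEAIFAPTYIMYWTRNITPESMIWYPAFICKWLD
YFAHRNYWAHAFSLKEEHWGCKTKMLSCKHCQFWLEEHLF
>RT_ref
LNMEEIPDMEKHQWDHGTCPLCKKRLFDGGQFINVESETKPDDGKLTANNRKHQQATGIH
CNLQLHKMTQPGTLGQLRDFNGSHECTQRIEGDIKIGQGNTPADSTCLKKYQGHCMPTQK
CVKLCPTKGSMRGIVRHRNRSMYFGICQPEHSYPPKVDDTQAEHQIFFPFQPPYHMLGMI
>RH_ref
IWFRHFHDFKIIVDSKGVAMQFKQVTIFNHTKTIAWMDFRNCEQRRHLQVADYHCMQLVA
NVKQDQPFRCIVMFKKQYEGMRFNYTYDRCNNFWVVYHDKDYTSQTQTYFRRFNYHAHWT
DAIWSWFATK
>INT_ref
MDQECHSMKTCGYHAFAMRTTMGFALDCFREDECYGEVPHWEPRKHAANLNNWIAWSCDD
EFQELVSVKMQFQWRGCMCVPQSQTKVKKSMTYKSDKYMVEGEHINCRVFATHKVKYRVY
IIQIKCIEEPLCTSSWYSQE
>CHROMO_ref
IFCRSEQDRIIWCRKADYQVHQFTRISPLFQFMHDMIEACDENAYLSILGIWFATYGYEA
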