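allele	groove_seq
A*01:01	FVKFVMSEEAQCTECKKNTHALPVVLTEGNPFYPDMMFEATVNGSSLAAK
A*02:01	FVKDVMSDEAQCTECKYNTRLLPAKTTEGNPFYPDMDFEATVNVSSLAGK
A*03:01	SVKDVMGDEAQCTECKYGTHALSVVTTEGNSFYPDTAFEADVNVSSLAAK
A*11:01	FVKDGMSDEAQCTECKYETHADPVVTWDGNPFKKDMMFEATVNVSNLAAC
A*24:02	FVKDVMSDEAQCPECKYNTHYSPVDPTEGVPFYPDRMFEATVNVSSLAAK
A*26:01	FVKDVMSDEAQCTECKYNTHALPDVTTIGNIFHPDHMFEVMVCVSSLAHK
A*31:01	FNKDVMSDEAQCTEDKYNTHALPVVTTEGNAWYPDMMFEATVNVSSLAAK
A*68:01	FDTDVMLDEAQCTECPYNTHALPFVTTPGNMFYPQMFFEATVNVSSLAAK
B*07:02	DERPLQVYDAGVSGMFRSCPPEMPSWPALHMYNMVPAPCWIGGPWRFFFC
B*08:01	GCCEKQVYRTGVYVMFLSNPPEMPSWMALDMYNPLPAPCWIGGPWRFFPC
B*15:01	HCCSKQVYHTGCPGMFLSCPPNCPSDMALHMPNMLPQPQWTGGPWRFWPT
B*18:01	GCCWKQVYHTGVPAKFLSCPPTMPSWMALHMYQMLPAPCWIGGPWVFQPC
B*35:01	GCAWKWVYHTGVPGMFKSRPPEMPSKMALTMYPMLPAICWGGGPWRFFPV
B*40:01	GCEEKQVARTGVPGMFLSCPPEMPSWMALYWYMMLFAPCWIYGPWRFFPC
B*44:02	GCCEKQVYATGVPGMFLSCPPEMPSWMALHAYNMLCAPCWIGGPWRFRPC
B*57:01	GCCELQVYCLQVPGMYLSCPPEMPSWHALHMYNMLPAPCWIGGPWRFLPC
C*03:04	SMHMEMMPRACACEGWDEKCHGKFKWQNNIEKMMSTNKPTCMCKQHHCPE
C*04:01	SMWAEMYPRAQATEGWPCKCHGKFIWVNNICFMVSTNYTTCRCKQHHCPE
C*05:01	SMHQEMYPRACACEGWPCKFHGKFIAVNNIEFMWSTNYPTCRCKQHHCPP
C*06:02	SMHAEMYPRACACEGWPQKCHGKVIWVNNIEFMWSTNYATCSCKRHHCPE
C*07:01	WMTAEMYAEACACYGWFCPCHGKFIWVNNIAWMWSTNYPTCRCKQHHCPE
C*07:02	GDHAEQYPRACACEGWPCKCHGKFFWVPNEEFQWSTNYPTCRCKMHHCPE
C*12:03	SMHAEMYPRACACEGWPCKCHGKFVWVNNIEFMWSNNYPTCGCKQHHCPE
C*16:01	NMFLERYPRACACEGWPCKCHGKKNWVVNIPFMGSTNYPTCRCKQHWCPE
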