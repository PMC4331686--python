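LY	LY[\ ]{0,1}[1-9][0-9]{5,6}
AMN	AMN[1-9][0-9]{2,4}
CHEBI	CHEBI:[1-9][0-9]{0,5}
CHEMBL	CHEMBL[1-9][0-9]{2,6}
DRUGBANK	DB[0-9]{5}
HMDB	HMDB[0-9]{5,7}
CAS	[1-9][0-9]{1,6}-[0-9]{2}-[0-9]
CID	CID[\ ]{0,1}[1-9][0-9]{3,8}
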