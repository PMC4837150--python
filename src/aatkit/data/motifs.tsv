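motif_id	width	sequence
1	152	KNHVIQWFEVLDGLLGPYWKALGLAFNCTFLLFGSVIQLIACASNIYYINDKLDKRTWTYIFGACCATTVFIPSFHNYRIWSFLGLGMTTYTAWYLAVAAILHGQVENVTHTGPTKLVLYFTGATNILYTFGGHAVTVEIMHAMWKPQKFKY
2	152	MLIHQFITFGFACTPLYFVWEKVIGMHDTKSICLRALARLPVVIPIWFLAIIFPFFGPINSAVGALLVSFTVYVIPACAHMLTYKSASARQNAAEKLPFFIPNWTAMYVVNAFVVVWVLVVGFGFGGWASMTNFIKQVDTFGLFAKCYQCPP
3	79	EAKTMKKATLISIAVTTTFYMLCGCMGYAAFGDAAPGNLLTGFGFYNPYWLIDIANAAIVIHLVGAYQVFSQPIFAFVE
4	39	KRTGTVWTASAHIITAVIGSGVLSLAWAIAQLGWIAGPI
5	41	RTVFVIITTVISMLLPFFNDILGVIGALGFWPLTVYFPVEM
6	43	FACIQIVLSQIPNFHKLWWLSIVAAVMSFAYSSIGLGLSVAKV
7	28	QAIGDIAFAYAYSNVLIEIQDTLKSSPP
8	28	VAYAVVALCYFPVGILGYWAFGNSVEDN
9	27	VEMHEMVPGKRFDRYHELGQHAFGEKL
10	28	LCGLVQYINLFGVAIGYTIAASTSMMAI
11	39	QKRTPRWSSRWIGMQILSVVCLIVSVAAAVGSVASIVLD
12	39	FFAYVGFDAVSTMAEETKNPARDIPIGLVGSMVITTLAY
13	39	EKPKWLIAMANMFVVIHVIGSYQIYAMPVFDMIETVMVK
14	164	CLLAVTLCLMQNYTDIDKDAPYSVAFSAVGMDWAKYIVAFGALKGMTTVLLVSAVGQARYLTHIARTHMMPPWFAHVDERTGTPMNATISMLAATAVIAFFTDLGILSNLLSISTLFIFMLVALALLVRRYYSSGLTTKENQVKLIVCLMLILGSSCAISAYWA
15	39	FAVICCYTATLMRYCFESREGITSYPDIGEAAFGKYGRI
16	71	ILQQWFGIHWWNSREFALLFTLVFVMLPLVLYKRVESLKYSSAVSTLLAVAFVGICCGLAITALVQGKTQT
17	39	YSLIGDTTNRLFGIFNAIPIIANTYGCGIVPEIQATLAP
18	55	PKAKEPKFWGVPLVPWIPSISIFINIFLLGSIDKDSFIRFGFWTVFLLVYYVFFG
19	20	NCYHKKGHEAPCKYGGNLYM
20	28	TLNMPKELVATKIAVWTTVVNPFTKYAL
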