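animal_id	location	origin	phenotype	18:14705518:T:C
FD001	Edersee	G	WT	TC
FD002	Edersee	G	WT	TC
FD003	Edersee	G	WT	TT
FD004	Edersee	G	WT	TT
FD005	Edersee	G	WT	TT
FD006	Edersee	G	WT	TT
FD007	Edersee	G	WT	TT
FD008	Edersee	G	WT	TT
FD009	Edersee	G	WT	TT
FD010	Edersee	G	WT	TT
FD011	Edersee	G	white	CC
FD012	Edersee	G	white	CC
FD013	Edersee	G	white	CC
FD014	Eulbach	G	WT	TC
FD015	Eulbach	G	WT	TC
FD016	Eulbach	G	WT	TT
FD017	Eulbach	G	WT	TT
FD018	Eulbach	G	WT	TT
FD019	Eulbach	G	WT	TT
FD020	Eulbach	G	WT	TT
FD021	Eulbach	G	WT	TT
FD022	Eulbach	G	WT	TT
FD023	Eulbach	G	WT	TT
FD024	Eulbach	G	WT	TT
FD025	Eulbach	G	WT	TT
FD026	Eulbach	G	WT	TT
FD027	Eulbach	G	WT	TT
FD028	Eulbach	G	WT	TT
FD029	Eulbach	G	WT	TT
FD030	Eulbach	G	WT	TT
FD031	Eulbach	G	WT	TT
FD032	Eulbach	G	dark pigmented	TT
FD033	Eulbach	G	white	CC
FD034	Eulbach	G	white	CC
FD035	Eulbach	G	white	CC
FD036	Griebelschied	G	white	CC
FD037	Griebelschied	G	white	CC
FD038	Hanstedt	G	WT	TC
FD039	Hanstedt	G	white	CC
FD040	Hanstedt	G	white	CC
FD041	Hanstedt	G	white	CC
FD042	Hanstedt	G	white	CC
FD043	Hanstedt	G	white	CC
FD044	Murowana	H	WT	TT
FD045	Weishauswald	G	WT	TC
FD046	Weishauswald	G	WT	TT
FD047	Weishauswald	G	WT	TT
FD048	Weishauswald	G	WT	TT
FD049	Weishauswald	G	WT	TT
FD050	Weishauswald	G	white	CC
FD051	Mueritz	H	WT	TC
FD052	Mueritz	H	WT	TT
FD053	Mueritz	H	white	CC
FD054	Neuruppin	H	WT	TT
FD055	Neuruppin	H	WT	TT
FD056	Neuruppin	H	WT	TT
FD057	Neuruppin	H	WT	TT
FD058	Neuruppin	H	WT	TT
FD059	Neuruppin	H	WT	TT
FD060	Neuruppin	H	WT	TT
FD061	Neuruppin	H	WT	TT
FD062	Neuruppin	H	WT	TT
FD063	Neuruppin	H	WT	TT
FD064	Neuruppin	H	WT	TT
FD065	Neuruppin	H	WT	TT
FD066	Neuruppin	H	WT	TT
FD067	Pleizenhausen	G	white	CC
FD068	Sababurg	G	WT	TC
FD069	Sababurg	G	WT	TC
FD070	Sababurg	G	WT	TC
FD071	Sababurg	G	WT	TT
FD072	Sababurg	G	WT	TT
FD073	Sababurg	G	WT	TT
FD074	Sababurg	G	WT	TT
FD075	Sababurg	G	WT	TT
FD076	Sababurg	G	WT	TT
FD077	Sababurg	G	WT	TT
FD078	Sababurg	G	WT	TT
FD079	Sababurg	G	WT	TT
FD080	Sababurg	G	WT	TT
FD081	Sababurg	G	WT	TT
FD082	Sababurg	G	WT	TT
FD083	Sababurg	G	WT	TT
FD084	Sababurg	G	WT	TT
FD085	Sababurg	G	WT	TT
FD086	Sababurg	G	WT	TT
FD087	Sababurg	G	WT	TT
FD088	Sababurg	G	WT	TT
FD089	Sababurg	G	WT	TT
FD090	Sababurg	G	dark pigmented	TT
FD091	Sababurg	G	dark pigmented	TT
FD092	Sababurg	G	white	CC
FD093	Sababurg	G	white	CC
FD094	Sababurg	G	white	CC
FD095	Sababurg	G	white	CC
FD096	Sababurg	G	white	CC
FD097	Weilburg	G	WT	TT
FD098	Weilburg	G	WT	TT
FD099	Wolfshagen	H	WT	TC
FD100	Wolfshagen	H	WT	TT
FD101	Wolfshagen	H	WT	TT
FD102	Wolfshagen	H	white	CC
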