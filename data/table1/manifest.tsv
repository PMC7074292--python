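accession	family	organism	path
AE001273.1	Chlamydiales	Chlamydia trachomatis D/UW-3/CX	AE001273.1.fasta
AE002160.2	Chlamydiales	Chlamydia muridarum Nigg	AE002160.2.fasta
AE009440.1	Chlamydiales	Chlamydophila pneumoniae TW-183	AE009440.1.fasta
AE015925.1	Chlamydiales	Chlamydophila caviae GPIC	AE015925.1.fasta
AP006861.1	Chlamydiales	Chlamydia felis Fe/C-56	AP006861.1.fasta
CP002549.1	Chlamydiales	Chlamydophila psittaci 6BC	CP002549.1.fasta
CP002608.1	Chlamydiales	Chlamydophila pecorum E58	CP002608.1.fasta
CP006571.1	Chlamydiales	Chlamydia avium 10DC88	CP006571.1.fasta
CP015840.1	Chlamydiales	Chlamydia gallinacea 08-1274/3	CP015840.1.fasta
CR848038.1	Chlamydiales	Chlamydophila abortus strain S26/3	CR848038.1.fasta
BA000031.2	Vibrionaceae	Vibrio parahaemolyticus RIMD 2210633	BA000031.2.fasta
BA000037.2	Vibrionaceae	Vibrio vulnificus YJ016	BA000037.2.fasta
CP000020.2	Vibrionaceae	Vibrio fischeri ES114	CP000020.2.fasta
CP000626.1	Vibrionaceae	Vibrio cholerae O395	CP000626.1.fasta
CP000789.1	Vibrionaceae	Vibrio harveyi ATCC BAA-1116	CP000789.1.fasta
CP002284.1	Vibrionaceae	Vibrio anguillarum 775	CP002284.1.fasta
CP002377.1	Vibrionaceae	Vibrio furnissii NCTC 11218	CP002377.1.fasta
CR354531.1	Vibrionaceae	Photobacterium profundum SS9	CR354531.1.fasta
FM178379.1	Vibrionaceae	Aliivibrio salmonicida LFI1238	FM178379.1.fasta
FM954972.2	Vibrionaceae	Vibrio splendidus LGP32	FM954972.2.fasta
AL590842.1	Yersiniaceae	Yersinia pestis CO92	AL590842.1.fasta
CP000720.1	Yersiniaceae	Yersinia pseudotuberculosis IP 31758	CP000720.1.fasta
CP000826.1	Yersiniaceae	Serratia proteamaculans 568	CP000826.1.fasta
CP002505.1	Yersiniaceae	Rahnella sp. Y9602	CP002505.1.fasta
CP002774.1	Yersiniaceae	Serratia sp. AS12	CP002774.1.fasta
CP006250.1	Yersiniaceae	Serratia plymuthica 4Rx13	CP006250.1.fasta
CP016940.1	Yersiniaceae	Yersinia enterocolitica strain YE5	CP016940.1.fasta
CP017236.1	Yersiniaceae	Yersinia ruckeri strain QMA0440 isolate 14/0165-5k	CP017236.1.fasta
HG738868.1	Yersiniaceae	Serratia marcescens SMB2099	HG738868.1.fasta
LN890288.1	Yersiniaceae	Serratia symbiotica strain STs	LN890288.1.fasta
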