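variant	genomic_printed	pos	ref	alt	impact	carriers	acmg_class	mm_p16	mm_p16g	mm_p12	mm_p14	flags
p14:c.161G>A (p.R54H)	chr9:21994170	21994170	G	A	missense	2	VUS-3B	-	-	-	n.a.	
p14:c.193+1G>A	chr9:21994136	21994137	G	A	Splicing	7	P					pos_discrepant
p16:c.-31G>C	chr9:21974857	21974857	G	C	5′UTR	1	VUS					
p16:c.-19G>C	chr9:21974845	21974845	G	C	5′UTR	1	VUS					
p16,p12,p16γ:c.51C>T (p.A17A)	chr9:21974776	21974776	C	T	silent	1	VUS					
p16,p12,p16γ:c.52_57delACGGCC (p.T18_A19del)	chr9:21974770_21974775	21974775	ACGGCC		in frame deletion	2	LP					
p16,p12,p16γ:c.71G>C (p.R24P)	chr9:21974756	21974756	G	C	missense	17	LP	Hd	Hd	Hd	-	
p16,p12,p16γ:c.79G>T (p.E27X)	chr9:21974748	21974748	G	T	truncating	1	P					
p16,p12,p16γ:c.132delC (p.Y44X)	chr9:21974695	21974695	C		truncating	1	P					
p16,p12,p16γ:c.142C>A (p.P48T)	chr9:21974685	21974685	C	A	missense	3	LP	Hd	Hd	Hd	-	
p16,p16γ:c.150+5G>T; p12:c.155G>T (p.G52V)	chr9:21974672	21974672	G	T	splicing/missense	1	VUS	-	-	Hd	-	
p16,p16γ:c.150+37G>C; p12:c.187G>C (p.G63R)	chr9:21974640	21974640	G	C	splicing/missense	3	VUS	-	-	Hd	-	
p16,p16γ:c.150+49A>T; p12:c.199A>T (p.R67W)	chr9:21974628	21974628	A	T	splicing/missense	1	VUS	-	-	Sd	-	
p16,p16γ:c.167G>T (p.S56I); p14:c.210G>T (p.Q70H)	chr9:21971191	21971191	G	T	missense	3	LP	D	Ss	-	n.a.	
p16,p16γ:c.176T>G (p.V59G); p14:c.219T>G (p.S73R)	chr9:21971182	21971182	T	G	missense	4	LP	Hd	Hd	-	n.a.	
p16,p16γ:c.191_194dupTGCT (p.H66Afs*55); p14:c.234_237dupTGCT (p.P80Cfs*82)	chr9:21971164_21971167	21971164		TGCT	truncating	1	P					
p16,p16γ:c.199G>C (p.G67R); p14:c.242G>C (p.R81P)	chr9:21971159	21971159	G	C	missense	3	VUS-3B	Hd	Hd	-	n.a.	
p16,p16γ:c.201delC (p.A68Rfs*78); p14:c.244delC (p.R82Afs*90)	chr9:21971157	21971157	C		truncating	1	P					
p16,p16γ:c.202_203delGCinsCT (p.A68L); p14:c.245_246delGCinsCT (p.R82P)	chr9:21971154	21971156	GC	CT	missense	2	VUS-3B	Hd	Hd	-	n.a.	pos_discrepant,alt_discrepant
p16,p16γ:c.212A>G (p.N71S); p14:c.255A>G (p.Q85Q)	chr9:21971146	21971146	A	G	missense	11	LP	Sd	Hd	-	n.a.	
p16,p16γ:c.212A>T (p.N71I); p14:c.255A>T (p.Q85H)	chr9:21971146	21971146	A	T	missense	5	LP	Ss	Ss	-	n.a.	alt_discrepant,excluded
p16,p16γ:c.249C>A (p.H83Q); p14:c.292C>A (p.R98R)	chr9:21971109	21971109	C	A	missense	2	VUS-3B	D	Hd	-	n.a.	
p16,p16γ:c.301G>T (p.G101W); p14:c.344G>T (p.R115L)	chr9:21971057	21971057	G	T	missense	16	LP	Hd	Hd	-	n.a.	
p16,p16γ:c.340C>T (p.P114S); p14:c.383C>T (p.A128V)	chr9:21971018	21971018	C	T	missense	1	LP	Hd	Hd	-	-	
p16,p16γ:c.377T>A (p.V126D)	chr9:21970981	21970981	T	A	missense	1	LP	Hd	Hd	-	-	
p16,p16γ:c.425A>G (p.H142R)	chr9:21970933	21970933	A	G	missense	1	VUS-3B	Sd	N	-	-	
p16,p16γ:c.430C>T (p.R144C)	chr9:21970928	21970928	C	T	missense	1	VUS	Sd	N	-	-	
p16,p16γ:c.436_437insG (p.D146Gfs*19)	chr9:21970922	21970922		G	truncating	1	LP					
p16γ:c.496C>T (p.H166Y)	chr9:21968732	21968732	C	T	missense	1	VUS	-	Ss	-	-	
p16:c.458-105A>G (p.156_157del)	chr9:21968346	21968346	A	G	in frame deletion	2	VUS-3B					excluded
p16γ:c.495G>C (p.R165S)	chr9:21968733	21968733	G	C	missense	1	VUS	-	D	-	-	
p16:c.*31G>A	chr9:21968197	21968197	G	A	3′UTR	1	VUS					
p16:c.*42C>A	chr9:21968186	21968186	C	A	3′UTR	1	VUS					
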