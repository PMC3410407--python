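# Degenerate protein motifs for genome-wide K+ transporter screening.
# Columns: motif_id <TAB> family_class <TAB> motif (dash-separated positions;
# 'x' = any residue, [A,B,...] = allowed residue set, single letter = fixed).
1	CHANNEL	[S,T]-x-x-T-x-G-[Y,F,L]-G-[D,E]
2	CHANNEL	R-[L,F]-x-R-[L,V,I,A,G]-x-[R,C,K]-[V,A,L,M]
3	CHANNEL	[A,V,S]-Y-[L,I]-[I,L]-G-[N,I]-[M,I]-T-[N,A]-L-[V,I]
4	HKT	[S,T,A]-x-[F,Y,V,L,C]-x-[D,N,S]-G
5	HKT	[G,A]-[Y,F]-[G,A]-x-[V,A,I]-G-[L,M,Y,F]-[S,T]
6	HAK	[A,G]-[D,S,G]-[V,L,I,M]-x-x-[S,A]-P-L-Y
7	HAK	[A,G]-[N,D,H,S]-[D,N]-x-G-[E,Q,D,N]-[A,G]
8	HAK	[A,G,S]-[D,N]-[G,S,A,C]-x-[L,I,V,F]-x-P-x-[V,I,L,M]-[A,S]
9	HAK	G-[S,A,T,C]-E-[A,G]-x-[F,Y]-A-[D,N,E]-[L,I,V]-[G,C,S,A]-x-F
10	HAK	[Y,F]-x-x-x-x-x-[H,F,Y]-G-Y-x-[E,D]
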