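# Synthetic reference SBS signature analogs (not the published COSMIC vectors).
# Shapes emulate: SBS1 (NpCpG C>T clock), SBS5 (flat clock-like), SBS18 (C>A oxidative),
# SBS34 (T>A at A/T homopolymer boundaries). Probability vectors over the 96 channels.
channel	SBS1_like	SBS5_like	SBS18_like	SBS34_like
A[C>A]A	0.0010869565	0.0072469809	0.018511005	0.00125
A[C>A]C	0.0010869565	0.0071807278	0.049095046	0.00125
A[C>A]G	0.0010869565	0.0081697374	0.10574251	0.00125
A[C>A]T	0.0010869565	0.0083461897	0.024736545	0.00125
C[C>A]A	0.0010869565	0.0083522427	0.02496298	0.00125
C[C>A]C	0.0010869565	0.0085622105	0.021872953	0.00125
C[C>A]G	0.0010869565	0.0082872354	0.015533611	0.00125
C[C>A]T	0.0010869565	0.0078810667	0.056770379	0.00125
G[C>A]A	0.0010869565	0.0092799072	0.072434208	0.00125
G[C>A]C	0.0010869565	0.0092783359	0.028783269	0.00125
G[C>A]G	0.0010869565	0.0081537045	0.029583221	0.00125
G[C>A]T	0.0010869565	0.0080484233	0.077941256	0.00125
T[C>A]A	0.0010869565	0.0091581436	0.12071562	0.00125
T[C>A]C	0.0010869565	0.0088791122	0.078045759	0.00125
T[C>A]G	0.0010869565	0.0088836223	0.139603	0.00125
T[C>A]T	0.0010869565	0.0093651456	0.055668644	0.00125
A[C>G]A	0.0010869565	0.0076117213	0.001	0.00125
A[C>G]C	0.0010869565	0.0086152099	0.001	0.00125
A[C>G]G	0.0010869565	0.0090266512	0.001	0.00125
A[C>G]T	0.0010869565	0.0095760839	0.001	0.00125
C[C>G]A	0.0010869565	0.0075684426	0.001	0.00125
C[C>G]C	0.0010869565	0.0076949078	0.001	0.00125
C[C>G]G	0.0010869565	0.0095404829	0.001	0.00125
C[C>G]T	0.0010869565	0.0085552981	0.001	0.00125
G[C>G]A	0.0010869565	0.0080031475	0.001	0.00125
G[C>G]C	0.0010869565	0.009457784	0.001	0.00125
G[C>G]G	0.0010869565	0.0086799691	0.001	0.00125
G[C>G]T	0.0010869565	0.0094744283	0.001	0.00125
T[C>G]A	0.0010869565	0.0087081263	0.001	0.00125
T[C>G]C	0.0010869565	0.007244221	0.001	0.00125
T[C>G]G	0.0010869565	0.0080683636	0.001	0.00125
T[C>G]T	0.0010869565	0.008628601	0.001	0.00125
A[C>T]A	0.0010869565	0.01197086	0.001	0.00125
A[C>T]C	0.0010869565	0.013205968	0.001	0.00125
A[C>T]G	0.225	0.010126644	0.001	0.00125
A[C>T]T	0.0010869565	0.011310819	0.001	0.00125
C[C>T]A	0.0010869565	0.011086105	0.001	0.00125
C[C>T]C	0.0010869565	0.010314641	0.001	0.00125
C[C>T]G	0.225	0.011125234	0.001	0.00125
C[C>T]T	0.0010869565	0.012309376	0.001	0.00125
G[C>T]A	0.0010869565	0.012948958	0.001	0.00125
G[C>T]C	0.0010869565	0.012729499	0.001	0.00125
G[C>T]G	0.225	0.012600107	0.001	0.00125
G[C>T]T	0.0010869565	0.011653976	0.001	0.00125
T[C>T]A	0.0010869565	0.011937772	0.001	0.00125
T[C>T]C	0.0010869565	0.01339628	0.001	0.00125
T[C>T]G	0.225	0.0129541	0.001	0.00125
T[C>T]T	0.0010869565	0.011994799	0.001	0.00125
A[T>A]A	0.0010869565	0.008820912	0.001	0.1265625
A[T>A]C	0.0010869565	0.008599729	0.001	0.0421875
A[T>A]G	0.0010869565	0.0076215592	0.001	0.0421875
A[T>A]T	0.0010869565	0.0084151341	0.001	0.1265625
C[T>A]A	0.0010869565	0.0074772215	0.001	0.0421875
C[T>A]C	0.0010869565	0.0080466045	0.001	0.0140625
C[T>A]G	0.0010869565	0.0073142575	0.001	0.0140625
C[T>A]T	0.0010869565	0.0088120255	0.001	0.0421875
G[T>A]A	0.0010869565	0.0089041989	0.001	0.0421875
G[T>A]C	0.0010869565	0.00915744	0.001	0.0140625
G[T>A]G	0.0010869565	0.0085829146	0.001	0.0140625
G[T>A]T	0.0010869565	0.0084070281	0.001	0.0421875
T[T>A]A	0.0010869565	0.008072601	0.001	0.1265625
T[T>A]C	0.0010869565	0.009299078	0.001	0.0421875
T[T>A]G	0.0010869565	0.008155055	0.001	0.0421875
T[T>A]T	0.0010869565	0.0088778104	0.001	0.1265625
A[T>C]A	0.0010869565	0.014566901	0.001	0.00125
A[T>C]C	0.0010869565	0.015007739	0.001	0.00125
A[T>C]G	0.0010869565	0.018077298	0.001	0.00125
A[T>C]T	0.0010869565	0.015291371	0.001	0.00125
C[T>C]A	0.0010869565	0.015782171	0.001	0.00125
C[T>C]C	0.0010869565	0.017540781	0.001	0.00125
C[T>C]G	0.0010869565	0.017176623	0.001	0.00125
C[T>C]T	0.0010869565	0.017432266	0.001	0.00125
G[T>C]A	0.0010869565	0.015168364	0.001	0.00125
G[T>C]C	0.0010869565	0.016751658	0.001	0.00125
G[T>C]G	0.0010869565	0.018284261	0.001	0.00125
G[T>C]T	0.0010869565	0.016039795	0.001	0.00125
T[T>C]A	0.0010869565	0.018481284	0.001	0.00125
T[T>C]C	0.0010869565	0.018626627	0.001	0.00125
T[T>C]G	0.0010869565	0.016864258	0.001	0.00125
T[T>C]T	0.0010869565	0.018251035	0.001	0.00125
A[T>G]A	0.0010869565	0.0075284635	0.001	0.00125
A[T>G]C	0.0010869565	0.0091542443	0.001	0.00125
A[T>G]G	0.0010869565	0.0088341172	0.001	0.00125
A[T>G]T	0.0010869565	0.0079438651	0.001	0.00125
C[T>G]A	0.0010869565	0.0073210984	0.001	0.00125
C[T>G]C	0.0010869565	0.0082193107	0.001	0.00125
C[T>G]G	0.0010869565	0.009505111	0.001	0.00125
C[T>G]T	0.0010869565	0.007385013	0.001	0.00125
G[T>G]A	0.0010869565	0.0079363827	0.001	0.00125
G[T>G]C	0.0010869565	0.0081131159	0.001	0.00125
G[T>G]G	0.0010869565	0.008645954	0.001	0.00125
G[T>G]T	0.0010869565	0.0075846187	0.001	0.00125
T[T>G]A	0.0010869565	0.0087928834	0.001	0.00125
T[T>G]C	0.0010869565	0.0089125613	0.001	0.00125
T[T>G]G	0.0010869565	0.0076853987	0.001	0.00125
T[T>G]T	0.0010869565	0.0093404973	0.001	0.00125
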