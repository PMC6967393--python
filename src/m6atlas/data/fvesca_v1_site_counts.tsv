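# Per-strand adenine and 6mA site counts, FraVesHawaii_1.0 assembly (25x coverage cutoff).
# NC_015206.1 is the chloroplast genome.
group	size	n_adenines_minus	n_adenines_plus	n_sites_minus	n_sites_plus
NC_020491.1	22681039	6567320	6591021	8952	9305
NC_020492.1	33308843	9638098	9648140	13054	13204
NC_020493.1	27879571	8167868	8116646	11122	10705
NC_020494.1	23292877	6727705	6722413	9208	9264
NC_020495.1	29328693	8565031	8576933	11920	11893
NC_020496.1	38222195	11129178	11162536	15731	15536
NC_020497.1	23403891	6867841	6891017	9155	9521
NC_015206.1	155691	49354	48400	883	803
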