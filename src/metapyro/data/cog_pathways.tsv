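cog_id	pathway	subcategory
COG0640	polysaccharide_degradation	cellulose
COG1472	polysaccharide_degradation	cellulose
COG2730	polysaccharide_degradation	cellulose
COG5297	polysaccharide_degradation	cellulose
COG3405	polysaccharide_degradation	cellulose
COG3664	polysaccharide_degradation	hemicellulose
COG3693	polysaccharide_degradation	hemicellulose
COG2115	polysaccharide_degradation	hemicellulose
COG1904	polysaccharide_degradation	hemicellulose
COG2368	polysaccharide_degradation	lignin
COG4638	polysaccharide_degradation	lignin
COG1014	acetogenesis	wood_ljungdahl
COG1152	acetogenesis	wood_ljungdahl
COG1614	acetogenesis	wood_ljungdahl
COG2069	acetogenesis	wood_ljungdahl
COG0674	acetogenesis	wood_ljungdahl
COG1456	acetogenesis	wood_ljungdahl
COG4624	methanogenesis	methyl_coenzyme_m_reductase
COG1229	methanogenesis	formylmethanofuran_dehydrogenase
COG1029	methanogenesis	formylmethanofuran_dehydrogenase
COG3259	methanogenesis	f420_hydrogenase
COG4074	methanogenesis	methyl_coenzyme_m_reductase
COG1927	methanogenesis	methyltransferase
COG4058	methanogenesis	methyl_coenzyme_m_reductase
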