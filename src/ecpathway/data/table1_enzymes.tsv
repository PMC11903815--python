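process	enzyme	ec_numbers	map_id	section
Butyrogenesis	Acetyl-CoA acetyltransferase	2.3.1.9	map00650	concordant
Butyrogenesis	3-hydroxybutyryl-CoA dehydrogenase	1.1.1.157	map00650	concordant
Butyrogenesis	Enoyl-CoA hydratase	4.2.1.17	map00650	concordant
Butyrogenesis	Butyryl-CoA dehydrogenase	1.3.8.1	map00650	concordant
Butyrogenesis	Phosphate butyryltransferase	2.3.1.19	map00650	concordant
Butyrogenesis	Butyrate kinase	2.7.2.7	map00650	concordant
Butyrogenesis	Glutamate decarboxylase	4.1.1.15	map00650	concordant
Butyrogenesis	4-hydroxybutyryl-CoA dehydratase/vinylacetyl-CoA-Delta-isomerase	5.3.3.3;4.2.1.120	map00650	concordant
Propionogenesis	Malate dehydrogenase	1.1.1.37	map00720	concordant
Propionogenesis	Fumarate hydratase	4.2.1.2	map00720	concordant
Propionogenesis	Fumarate reductase flavoprotein	1.3.1.6	map00720	concordant
Propionogenesis	Methylmalonyl-CoA mutase	5.4.99.2	map00720	concordant
Propionogenesis	Propionyl-CoA carboxylase	6.4.1.3	map00720	concordant
Propionogenesis	Acryloyl-CoA reductase	1.3.1.95	map00640	concordant
Propionogenesis	Lactaldehyde reductase	1.1.1.77	map00640	concordant
Propionogenesis	propanediol dehydratase	4.2.1.28	map00640	concordant
Propionogenesis	Phosphate propanoyltransferase	2.3.1.222	map00640	concordant
Acetogenesis	Carbon monoxide dehydrogenase	1.2.7.4	map00720	concordant
Acetogenesis	Carbon monoxide dehydrogenase/acetyl-CoA synthase	6.2.1.1	map00650	concordant
Acetogenesis	Formate-tetrahydrofolate ligase	6.3.4.3	map00720	concordant
Acetogenesis	Methenyltetrahydrofolate cyclohydrolase	3.5.4.9	map00720	concordant
Acetogenesis	Tetrahydrofolate dehydrogenase/cyclohydrolase	1.5.1.3	map00790	concordant
Acetogenesis	Phosphate acetyltransferase	2.3.1.8	map00720	concordant
Acetogenesis	Acetate kinase	2.7.2.1	map00720	concordant
Butyrogenesis	(R)-2-hydroxyglutaryl-CoA dehydratase	4.2.1.167	None	not_reported
Butyrogenesis	Glutaconyl-CoA decarboxylase	7.2.4.5	map00650	not_reported
Butyrogenesis	NAD-dependent 4-hydroxybutyrate dehydrogenase	1.1.1.61	map00650	not_reported
Butyrogenesis	4-hydroxybutyrate coenzyme A transferase	2.8.3.-	map00650	not_reported
Propionogenesis	Propionyl-CoA:succinate CoA transferase	2.8.3.1	map00640	not_reported
Butyrogenesis	Butyryl-CoA:acetate CoA-transferase	2.8.3.8	map00650	discordant
Butyrogenesis	Glutaconate CoA-transferase	2.8.3.12	map00650	discordant
Propionogenesis	Lactoyl-CoA dehydratase	4.2.1.54	map00640	discordant
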