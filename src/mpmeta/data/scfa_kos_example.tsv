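# Editable example list of KO enzymes for short-chain fatty acid biosynthesis
# attribution matrices (acetogenesis via the Wood-Ljungdahl pathway,
# propionogenesis, and the acetyl-CoA butyrogenic pathway).  The biochemical
# curation of which enzymes constitute each sub-pathway is an input, not code;
# edit this file to change the panel.
K01938	formate--tetrahydrofolate ligase	acetogenesis
K01491	methylenetetrahydrofolate dehydrogenase (NADP+)	acetogenesis
K00297	methylenetetrahydrofolate reductase (NADPH)	acetogenesis
K00198	anaerobic carbon-monoxide dehydrogenase	acetogenesis
K00625	phosphate acetyltransferase	acetogenesis
K00925	acetate kinase	acetogenesis
K01847	methylmalonyl-CoA mutase	propionogenesis
K01026	propionate CoA-transferase	propionogenesis
K00074	3-hydroxybutyryl-CoA dehydrogenase	butyrogenesis
K01715	enoyl-CoA hydratase (crotonase)	butyrogenesis
K00248	butyryl-CoA dehydrogenase	butyrogenesis
K00634	phosphate butyryltransferase	butyrogenesis
K00929	butyrate kinase	butyrogenesis
K01034	acetate CoA/acetoacetate CoA-transferase alpha subunit	butyrogenesis
K01035	acetate CoA/acetoacetate CoA-transferase beta subunit	butyrogenesis
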