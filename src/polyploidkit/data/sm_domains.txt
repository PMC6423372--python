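# Pfam domains commonly associated with plant specialized (secondary)
# metabolism. User-replaceable: pass your own list to annotate_metamodules
# or the `coexpress` CLI to override.
PF00067  # Cytochrome P450
PF00201  # UDP-glucoronosyl/UDP-glucosyl transferase
PF00195  # Chalcone/stilbene synthase, N-terminal
PF02797  # Chalcone/stilbene synthase, C-terminal
PF02431  # Chalcone-flavanone isomerase
PF00891  # O-methyltransferase domain
PF08100  # Dimerisation domain (plant OMT)
PF02458  # Transferase family (HXXXD acyltransferases, HCT/HQT)
PF00106  # Short-chain dehydrogenase/reductase
PF03055  # Retinal pigment epithelial membrane protein (CCD)
PF00296  # Luciferase-like monooxygenase
PF01397  # Terpene synthase, N-terminal
PF03936  # Terpene synthase family, metal binding
PF00494  # Squalene/phytoene synthase
PF01040  # UbiA prenyltransferase
PF00107  # Zinc-binding dehydrogenase (CAD)
PF08240  # Alcohol dehydrogenase GroES-like
PF02373  # JmjC domain (2OG-Fe(II) oxygenases)
PF03171  # 2OG-Fe(II) oxygenase superfamily (ANS/FLS/F3H)
PF14226  # DIOX_N, non-haem dioxygenase N-terminal
PF00155  # Aminotransferase class I and II
PF01063  # Amino-transferase class IV
PF00755  # Carnitine/choline acetyltransferase (BAHD-like)
PF13561  # Enoyl-(ACP) reductase
PF00561  # Alpha/beta hydrolase fold
PF01764  # Lipase (class 3)
PF00082  # Subtilase family
PF03321  # GH3 auxin-responsive promoter
PF00141  # Peroxidase
PF07732  # Multicopper oxidase (laccase)
PF00394  # Multicopper oxidase
PF00198  # 2-oxoacid dehydrogenase acyltransferase
PF00725  # 3-hydroxyacyl-CoA dehydrogenase
PF02771  # Acyl-CoA dehydrogenase, N-terminal
PF01553  # Acyltransferase
PF01073  # 3-beta hydroxysteroid dehydrogenase/isomerase
PF05834  # Lycopene cyclase
PF00834  # Ribulose-phosphate 3 epimerase family
PF00332  # Glycosyl hydrolases family 17
PF00232  # Glycosyl hydrolase family 1
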