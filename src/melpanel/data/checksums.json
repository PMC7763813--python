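{
 "README.md": "19c2c3b92b73aab7b5577082c5a6637e33adcc563ef0c9ff5a1d29ca4f5570f7",
 "bap1_model.yaml": "e0f8e133b83bc1bb8cc38b9dfdf821716acb1bfd167660382f5cdfe1dd1b3899",
 "cdk4_model.yaml": "816245882866016ba174cf2602c591ca3329efb990bc5390b000777f8a7be44d",
 "cdkn2a_model.yaml": "c45c56f7c6c88ad47a4b893f01296a3fbea29cee2e78470c577176f6fca225f3",
 "gene_positive_counts.tsv": "273fc4f52bb25c31d31d372c5783b90652e2eeb8bbc7b04c6fa8eb0a17ebf119",
 "mitf_model.yaml": "eb4e5d9b8e3fd0972737f900fedf16da9507073c3fd8c215747fa77bdd0021f3",
 "panel_loci.fasta": "d6172f4efe59a37fd78131874f1b97e20cb408e2711599bf48d50fec919777e4",
 "pot1_model.yaml": "07ef8773c4d89b2c04a9d82fa074a84f33b99d66db87d9637cfa6c2c6e245f77",
 "primers.tsv": "dcf0ffbe40dcd51d6dd12a2bccd5351249b20aaf67b66233143fa3d3aef5dc0c",
 "strata_counts.tsv": "a1d86e10a6a093d3a2b077ab2aba4bed912ce002beae7b91e64ae3d255ea8c76",
 "table2_cohort.tsv": "6b548ed18fe28c2e4ab6bb1265eaeff62bdd9272e1a6fece83e8b3286fd8ce8c",
 "table3_variants.tsv": "faaa19887c431b8a5d89e693005f96cb9c35e2566dce2c1ef06ed6b90f368e52"
}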