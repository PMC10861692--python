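{
  "description": "Reference convergence/divergence classification of key events in the 13-AOP nephrotoxicity network (AOP-Wiki snapshot of 2023-05-01), for cross-checking degree-based classification once the full curated KER table is ingested.",
  "convergent": [
    {"ke_type": "KE", "title": "Occurrence, tubular necrosis"},
    {"ke_type": "MIE/KE", "title": "Increase, cytotoxicity"},
    {"ke_type": "KE", "title": "Increase, oxidative stress"},
    {"ke_type": "KE", "title": "Increased sodium-sensitive hypertension"},
    {"ke_type": "KE/AO", "title": "Increased, kidney failure"},
    {"ke_type": "KE/AO", "title": "Occurrence, kidney toxicity"},
    {"ke_type": "KE", "title": "Increase, apoptosis"},
    {"ke_type": "KE", "title": "Increased blood uric acid concentration"},
    {"ke_type": "AO", "title": "Chronic kidney disease"},
    {"ke_type": "AO", "title": "Increased mortality"},
    {"ke_type": "AO", "title": "Increase, adenomas/carcinomas"}
  ],
  "divergent": [
    {"ke_type": "KE", "title": "Increase, Mt dysfunction"},
    {"ke_type": "KE", "title": "Increased, ROS"},
    {"ke_type": "KE", "title": "Increase, lipid peroxidation"},
    {"ke_type": "KE", "title": "Altered NRF2 antioxidant pathway"},
    {"ke_type": "MIE", "title": "Inhibition, mtETC complexes"},
    {"ke_type": "MIE", "title": "Alkylation, protein"},
    {"ke_type": "MIE", "title": "Increased, Binding of chemicals to 2u"},
    {"ke_type": "MIE", "title": "Inhibition, OAT1"},
    {"ke_type": "MIE", "title": "Binding of substrate endocytic receptor"},
    {"ke_type": "MIE", "title": "Inhibition of mtDNA (Pol gamma)"},
    {"ke_type": "MIE", "title": "Binding, thiol proteins/selenoproteins"},
    {"ke_type": "MIE", "title": "Inhibition, COX1 activity"},
    {"ke_type": "MIE", "title": "Hyperactivation of ACE/Ang-II, AT1R axis"}
  ]
}
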