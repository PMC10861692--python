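aop_id,title,mie_title,ao_title,oecd_status,source_url
105,Alpha_2u_-microglobulin cytotoxicity leading to renal tubular adenomas and carcinomas (in male rat),"Increased, binding of chemicals to α2u (serum)","Increase, adenomas/carcinomas (renal tubular)",,https://aopwiki.org/aops/105
116,Cytotoxicity leading to renal tubular adenomas and carcinomas (in male rat),"Increase, cytotoxicity (tubular epithelial cells)","Increase, adenomas/carcinomas (renal tubular)",,https://aopwiki.org/aops/116
138,Organic anion transporter (OAT1) inhibition leading to renal failure and mortality,"Inhibition, organic anion transporter 1 (OAT1)","Increased mortality and decline, population",,https://aopwiki.org/aops/138
177,Cyclooxygenase 1 (COX1) inhibition leading to renal failure and mortality,"Inhibition, cyclooxygenase 1 activity","Increased mortality and decline, population",,https://aopwiki.org/aops/177
186,Unknown MIE leading to renal failure and mortality,"Unknown, MIE",Increased mortality,,https://aopwiki.org/aops/186
256,Inhibition of mitochondrial DNA polymerase gamma leading to kidney toxicity,Inhibition of mitochondrial DNA polymerase gamma (Pol gamma),"Occurrence, kidney toxicity",Under development,https://aopwiki.org/aops/256
257,Receptor-mediated endocytosis and lysosomal overload leading to kidney toxicity,"Binding of substrate, endocytic receptor","Occurrence, kidney toxicity",Under development,https://aopwiki.org/aops/257
258,Renal protein alkylation leading to kidney toxicity,"Alkylation, protein","Occurrence, kidney toxicity",Under development,https://aopwiki.org/aops/258
284,Binding of electrophilic chemicals to SH(thiol)-group of proteins and/or to selenoproteins involved in protection against oxidative stress leads to chronic kidney disease,"Binding, thiol proteins/selenoproteins involved in protection against oxidative stress",Chronic kidney disease,,https://aopwiki.org/aops/284
384,Hyperactivation of ACE/Ang-II/AT1R axis leading to chronic kidney disease,Hyperactivation of ACE/Ang-II/AT1R axis,Chronic kidney disease,,https://aopwiki.org/aops/384
413,Oxidation and antagonism of reduced glutathione leading to mortality via acute renal failure,"Oxidation, glutathione",Increased kidney failure and mortality,,https://aopwiki.org/aops/413
437,Inhibition of mitochondrial electron transport chain (ETC) complexes leading to kidney toxicity,"Inhibition, mitochondrial electron transport chain complexes","Occurrence, kidney toxicity",,https://aopwiki.org/aops/437
447,"Kidney failure induced by inhibition of mitochondrial electron transfer chain through apoptosis, inflammation, and oxidative stress pathways","Inhibition, mitochondrial electron transport chain complexes","Increased, kidney failure",,https://aopwiki.org/aops/447
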