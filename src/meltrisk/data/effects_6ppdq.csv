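compound_id,bqe,ec50_mg_L,species,reference
6-PPDQ,fish,0.000095,Oncorhynchus kisutch,24 h juvenile coho salmon exposure
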