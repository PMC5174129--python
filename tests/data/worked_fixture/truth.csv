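feature_id,feature_type,role,anchor_metabolite,pathway,trait,planted_effects
gene_0013,gene,candidate,met_0001,osa00940,,A:1;B:1.143;C:1.571;D:1.857;E:2;F:1.143
gene_0010,gene,candidate,met_0000,osa00941,,A:-1;B:-1.15;C:-1.75;D:-2;E:-1.75;F:-1.1
gene_0003,gene,responsive,,,,A:2;B:2;C:2;D:2;E:2;F:0
gene_0016,gene,responsive,,,,A:2;B:2;C:2;D:2;E:2;F:0
gene_0007,gene,developmental,,,,A:0;B:0.4;C:0.8;D:1.2;E:1.6;F:2
gene_0012,gene,developmental,,,,A:-0;B:-0.4;C:-0.8;D:-1.2;E:-1.6;F:-2
met_0001,metabolite,key,,osa00940,osmolality,coupling:1.5
met_0000,metabolite,key,,osa00941,aoc,coupling:1.5
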