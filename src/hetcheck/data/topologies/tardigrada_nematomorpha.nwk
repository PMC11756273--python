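(Outgroup:0.40,((Priapulida:0.18,(Kinorhyncha:0.22,Loricifera:0.25):0.06):0.08,((Nematoda:0.55,(Nematomorpha:0.50,Tardigrada:0.60):0.07):0.10,(Onychophora:0.20,Arthropoda:0.17):0.06):0.04):0.12);
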