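role	smarts
donor	[$([N;!H0;v3,v4&+1]),$([O,S;H1;+0]),n&H1&+0]
acceptor	[$([O,S;H1;v2;!$(*-*=[O,N,P,S])]),$([O,S;H0;v2]),$([O,S;-]),$([N;v3;!$(N-*=[O,N,P,S])]),$([nH0;+0]),$([o;+0]),$([s;+0])]
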