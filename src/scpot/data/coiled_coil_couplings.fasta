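>cc_aa_chainA dimeric parallel coiled coil, a-a' core coupling system; interacting pair (A16, B16); position 16 is leucine in the modeled reference
RAAFLEKENTALRTRLAELRKRVGRCRNIVSKYETRYG
>cc_aa_chainB a-a' system partner chain; interacting pair (A16, B16)
RAAFLEKENTALRTELAELEKEVGRCENIVSKYETRYG
>cc_ge_chainA g-e' interfacial coupling system (homodimer, both chains identical); interacting pair (A41, B46)
KVFVPDEQKDEKYWTRRKKNNVAAKRSRDARRLKENQITIRAAFLEKENTALRTEVAELRKEVGRCKNIVSKYETRYGPL
>cc_ge_chainB g-e' system partner chain (identical sequence); interacting pair (A41, B46)
KVFVPDEQKDEKYWTRRKKNNVAAKRSRDARRLKENQITIRAAFLEKENTALRTEVAELRKEVGRCKNIVSKYETRYGPL
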