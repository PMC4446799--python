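((((((((human:6,chimpanzee:6):3,gorilla:9):7,orangutan:16):13,(rhesus:12,baboon:12):17):14,(marmoset:20,squirrel_monkey:20):23):47,(mouse:25,rat:25):65):6,cattle:96):63,(opossum:88,wallaby:88):71);
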