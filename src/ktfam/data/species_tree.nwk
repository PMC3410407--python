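(Ppatens:1,(Smoellendorffii:1,(Osativa:1,(Athaliana:1,Ptrichocarpa:1):1):1):1);
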