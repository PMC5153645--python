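(Chelicerata,(Myriapoda,(Crustacea,(Protura,(Collembola,(Diplura,(Archaeognatha,(Zygentoma,((Odonata,Ephemeroptera),((Zoraptera,(Dermaptera,(Plecoptera,(Orthoptera,(Mantophasmatodea,(Grylloblattodea,(Embioptera,(Phasmatodea,(Mantodea,(Blattodea,Isoptera)))))))))),((Thysanoptera,(Hemiptera,Psocodea)),(Hymenoptera,(((Raphidioptera,(Megaloptera,Neuroptera)),(Strepsiptera,Coleoptera)),((Trichoptera,Lepidoptera),((Siphonaptera,Mecoptera),Diptera)))))))))))))));
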