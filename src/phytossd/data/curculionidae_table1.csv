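species,family,dose_gy,n_treated,highest_fail_dose_gy,source
Anthonomus grandis,Curculionidae,100,120,,Earle et al.
Blosyrus asellus,Curculionidae,25,15,,Follett et al.
Conotrachelus nenuphar,Curculionidae,92,25000,,Hallman
Conotrachelus nenuphar,Curculionidae,80,8,,Jacklin et al.
Cryphalus fulvus,Curculionidae,150,50,,Yoshida et al.
Cylas formicarius elegantulus,Curculionidae,150,62623,,Follett
Diaprepes abbreviatus,Curculionidae,50,220,,Gould & Hallman
Euscepes postfasciatus,Curculionidae,150,62323,,Follett
Hylurgus ligniperda,Curculionidae,175,60,,van Haandel et al.
Hypera postica,Curculionidae,80,30,,Burgess & Bennett
Hypothenemus hampei,Curculionidae,100,6598,,Follett
Hypothenemus hampei,Curculionidae,75,138,,Follett
Ips confusus,Curculionidae,150,30,,Wood & Stark
Ips sexdentatus,Curculionidae,140,,,Wang et al.
Ips subelongatus,Curculionidae,140,,,Zhan et al.
Naupactus xanthographus,Curculionidae,250,60,,Gerstle & Sazo
Orchidophilus aterrimus,Curculionidae,150,10,,Manoto et al.
Phlyctinus callosus,Curculionidae,80,200,,Duvenhage & Johnson
Pissodes strobi,Curculionidae,44,40,,Jaynes & Godwin
Sitophilus granarius,Curculionidae,100,80,,Aldryhim & Adam
Sitophilus oryzae,Curculionidae,120,32025,,Follett et al.
Sitophilus zeamais,Curculionidae,70,280,,Hu et al.
Sphenophorus levis,Curculionidae,25,100,,Arthur & Wiendl
Sternochetus frigidus,Curculionidae,109,1480,,Obra et al.
Sternochetus mangiferae,Curculionidae,100,76,,Follett
Sternochetus mangiferae,Curculionidae,50,60,,Seo et al.
Xyleborus atratus,Curculionidae,50,12,,Yoshida et al.
Xyleborus perforans,Curculionidae,50,12,,Yoshida et al.
Xylosandrus compactus,Curculionidae,40,12,,Yoshida et al.
Xylosandrus crassiusculus,Curculionidae,40,12,,Yoshida et al.
Xylosandrus germanus,Curculionidae,40,12,,Yoshida et al.
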