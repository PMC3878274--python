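order,family,species,common_name,iucn
Galliformes,Phasianidae,Arborophila ardens,Hainan Partridge,VU
Galliformes,Phasianidae,Arborophila gingica,White-necklaced Partridge,NT
Galliformes,Phasianidae,Arborophila rufipectus,Sichuan Partridge,EN
Galliformes,Phasianidae,Lophophorus lhuysii,Chinese Monal,VU
Galliformes,Phasianidae,Alectoris magna,Przevalski's Partridge,LC
Galliformes,Phasianidae,Tragopan caboti,Cabot's Tragopan,VU
Galliformes,Phasianidae,Syrmaticus ellioti,Elliot's Pheasant,NT
Galliformes,Phasianidae,Syrmaticus reevesii,Reeves's Pheasant,VU
Galliformes,Phasianidae,Tetraophasis obscurus,Verreaux's Monal-Partridge,LC
Passeriformes,Certhiidae,Certhia tianquanensis,Sichuan Treecreeper,NT
Passeriformes,Muscicapidae,Phoenicurus alaschanicus,Przevalski's Redstart,NT
Passeriformes,Leiothrichidae,Garrulax davidi,Plain Laughingthrush,LC
Passeriformes,Leiothrichidae,Babax koslowi,Tibetan Babax,NT
Passeriformes,Sittidae,Sitta yunnanensis,Yunnan Nuthatch,NT
Passeriformes,Leiothrichidae,Garrulax bieti,White-speckled Laughingthrush,VU
Passeriformes,Sylviidae,Chrysomma poecilotis,Rufous-tailed Babbler,LC
Passeriformes,Aegithalidae,Aegithalos fuliginosus,Sooty Bushtit,LC
Passeriformes,Corvidae,Perisoreus internigrans,Sichuan Jay,VU
Passeriformes,Sylviidae,Paradoxornis paradoxus,Three-toed Parrotbill,LC
Passeriformes,Sylviidae,Paradoxornis conspicillatus,Spectacled Parrotbill,LC
Passeriformes,Sylviidae,Paradoxornis przewalskii,Przevalski's Parrotbill,VU
Passeriformes,Sylviidae,Paradoxornis zappeyi,Grey-hooded Parrotbill,VU
Passeriformes,Corvidae,Podoces biddulphi,Biddulph's Ground Jay,NT
Passeriformes,Leiothrichidae,Garrulax elliotii,Elliot's Laughingthrush,LC
Passeriformes,Cisticolidae,Rhopophilus pekinensis,Chinese Hill Warbler,LC
Passeriformes,Leiothrichidae,Garrulax sukatschewi,Snowy-cheeked Laughingthrush,VU
Passeriformes,Aegithalidae,Leptopoecile elegans,Crested Tit-warbler,LC
Passeriformes,Fringillidae,Carpodacus roborowskii,Tibetan Rosefinch,LC
Passeriformes,Urocynchramidae,Urocynchramus pylzowi,Przevalski's Finch,LC
Passeriformes,Fringillidae,Carpodacus eos,Stresemann's Rosefinch,LC
Passeriformes,Pellorneidae,Alcippe variegaticeps,Golden-fronted Fulvetta,VU
Passeriformes,Pellorneidae,Alcippe striaticollis,Chinese Fulvetta,LC
Passeriformes,Phylloscopidae,Phylloscopus hainanus,Hainan Leaf Warbler,VU
Passeriformes,Phylloscopidae,Phylloscopus kansuensis,Gansu Leaf Warbler,LC
Passeriformes,Phylloscopidae,Phylloscopus emeiensis,Emei Leaf Warbler,LC
Galliformes,Phasianidae,Bonasa sewerzowi,Chinese Grouse,NT
Passeriformes,Leiothrichidae,Garrulax lunulatus,Barred Laughingthrush,LC
Passeriformes,Leiothrichidae,Garrulax maximus,Giant Laughingthrush,LC
Passeriformes,Oriolidae,Oriolus mellianus,Silver Oriole,VU
Passeriformes,Paridae,Parus davidi,Père David's Tit,LC
Passeriformes,Emberizidae,Emberiza koslowi,Tibetan Bunting,NT
Passeriformes,Emberizidae,Latoucheornis siemsseni,Slaty Bunting,LC
Passeriformes,Leiothrichidae,Liocichla omeiensis,Emei Shan Liocichla,VU
Passeriformes,Paridae,Parus superciliosus,White-browed Tit,LC
Galliformes,Phasianidae,Chrysolophus pictus,Golden Pheasant,LC
Passeriformes,Paridae,Parus venustulus,Yellow-bellied Tit,LC
Galliformes,Phasianidae,Crossoptilon auritum,Blue Eared Pheasant,LC
Galliformes,Phasianidae,Crossoptilon mantchuricum,Brown Eared Pheasant,VU
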