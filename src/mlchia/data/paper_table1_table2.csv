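name,log_pmw,psa,hia_percent,role,hia_reference
Acetaminophen,1.31,49.3,100,validation,Castillo-Garit et al. 2008
Acetylsalicylic acid,1.74,63.6,82,train,Castillo-Garit et al. 2008
Caffeine,0.93,58.4,99,train,Yan Wang & Cai 2008
Carbamazepine,2.39,46.3,84,train,Dressman Amidon & Fleisher 1985; Varma Sateesh & Panchagnula 2005
Cimetidine,1.97,88.89,68,train,Castillo-Garit et al. 2008; Linnankoski et al. 2006
Diclofenac,2.94,49.3,54,train,Veber et al. 2002
Fenoprofen,2.52,46.5,85,train,Hou Wang Zhang & Xu 2007
Fluconazole,1.40,81.6,94,train,Newby Freitas & Ghafourian 2015
Flurbiprofen,2.55,37.3,92,train,Raevsky 2008
Ibuprofen,1.52,37.3,98,validation,Newby Freitas & Ghafourian 2015
Ketoprofen,1.58,54.4,95,train,Newby Freitas & Ghafourian 2015
Naproxen,2.37,46.5,94,train,Castillo-Garit et al. 2008
Nicotinic acid,1.55,50.2,94,train,Newby Freitas & Ghafourian 2015
Phenylbutazone,2.15,40.6,94,train,Hou et al. 2007; Veber et al. 2002
Salicylic acid,1.69,57.5,99,validation,Raevsky 2008
Terbutaline,2.96,72.7,25,train,Gres et al. 1998
Theophylline,1.02,69.3,98,train,Kansy Senner & Gubernator 1998
Zolmitriptan,2.30,57.4,92,train,Newby Freitas & Ghafourian 2015
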