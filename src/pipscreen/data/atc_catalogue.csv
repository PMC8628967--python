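code,label,eu7_pim,withdrawn
N05BA01,diazepam,1,0
N05BA02,chlordiazepoxide,1,0
N05BA05,potassium clorazepate,1,0
N05BA12,alprazolam,1,0
N05CD01,flurazepam,1,0
N05CD02,nitrazepam,1,0
N05CF01,zopiclone,1,0
N05CF02,zolpidem,1,0
N05AA01,chlorpromazine,1,0
N05AB03,perphenazine,1,0
N05AD01,haloperidol,1,0
N05AG02,pimozide,0,0
N05BB01,hydroxyzine,1,0
N06AA04,clomipramine,1,0
N06AA09,amitriptyline,1,0
N06AA12,doxepin,1,0
N06AB03,fluoxetine,1,0
N06AB06,sertraline,0,0
N06AX05,trazodone,0,0
N06AX11,mirtazapine,0,0
N06AF03,phenelzine,0,0
N06AF04,tranylcypromine,0,0
N04AA01,trihexyphenidyl,1,0
N02AB02,pethidine,1,0
N02AC04,dextropropoxyphene,0,1
N02BE01,paracetamol,0,0
N02CA02,ergotamine,0,0
N02CC01,sumatriptan,0,0
A02AD01,aluminium-magnesium antacid,0,0
A02BC01,omeprazole,0,0
A03BA01,atropine,1,0
A03BB01,butylscopolamine,1,0
A06AD11,lactulose,0,0
A06AD15,macrogol,0,0
A08AA10,sibutramine,0,1
A08AX01,rimonabant,0,1
A10BA02,metformin,0,0
A10BB01,glibenclamide,1,0
A10BB02,chlorpropamide,0,0
A10BX06,benfluorex,0,1
A11DA01,thiamine,0,0
A11GA01,ascorbic acid,0,0
A11CC05,colecalciferol,0,0
A12AA04,calcium carbonate,0,0
A12BA01,potassium chloride,0,0
B01AA03,warfarin,0,0
B01AC06,acetylsalicylic acid,0,0
B03AA07,ferrous sulfate,0,0
B03BA01,cyanocobalamin,0,0
B03BB01,folic acid,0,0
C01AA05,digoxin,1,0
C01BD01,amiodarone,1,0
C01DA02,glyceryl trinitrate,0,0
C01DA08,isosorbide dinitrate,0,0
C01DA14,isosorbide mononitrate,0,0
C02AC01,clonidine,1,0
C03CA01,furosemide,0,0
C03CA02,bumetanide,0,0
C03DA01,spironolactone,0,0
C04AD03,pentoxifylline,1,0
C07AA07,sotalol,0,0
C07AB02,metoprolol,0,0
C07AB07,bisoprolol,0,0
C08CA01,amlodipine,0,0
C08DA01,verapamil,0,0
C09AA02,enalapril,0,0
C10AA01,simvastatin,0,0
C10AA05,atorvastatin,0,0
D01AC01,clotrimazole,0,0
G04BD04,oxybutynin,1,0
G04BE03,sildenafil,0,0
G04BE08,tadalafil,0,0
G04BE09,vardenafil,0,0
G04CA02,tamsulosin,0,0
G04CB01,finasteride,0,0
H03AA01,levothyroxine,0,0
J01CA04,amoxicillin,0,0
J01EA01,trimethoprim,0,0
J01EE01,sulfamethoxazole-trimethoprim,0,0
J01FA09,clarithromycin,0,0
L04AX01,azathioprine,0,0
L04AX03,methotrexate,0,0
M01AA01,phenylbutazone,1,0
M01AB01,indometacin,1,0
M01AB05,diclofenac,1,0
M01AC01,piroxicam,1,0
M01AE01,ibuprofen,0,0
M01AH02,rofecoxib,0,1
M01AH04,valdecoxib,0,1
M01AH05,etoricoxib,1,0
M01AX17,nimesulide,0,1
M02AA15,topical diclofenac,0,0
M03BX07,tetrazepam,0,1
M04AA01,allopurinol,0,0
M04AC01,colchicine,0,0
M05BA04,alendronic acid,0,0
N07CA01,betahistine,0,0
R03AC02,salbutamol,0,0
R03BB04,tiotropium bromide,0,0
R06AA02,diphenhydramine,1,0
R06AB04,chlorphenamine,1,0
R06AD02,promethazine,1,0
S01XA20,artificial tears,0,0
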