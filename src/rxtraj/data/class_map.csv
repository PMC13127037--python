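drug,med_class
sertraline,antidepressant
fluoxetine,antidepressant
citalopram,antidepressant
escitalopram,antidepressant
paroxetine,antidepressant
venlafaxine,antidepressant
duloxetine,antidepressant
bupropion,antidepressant
mirtazapine,antidepressant
trazodone,antidepressant
haloperidol,FGA
chlorpromazine,FGA
perphenazine,FGA
fluphenazine,FGA
quetiapine,SGA
aripiprazole,SGA
risperidone,SGA
olanzapine,SGA
ziprasidone,SGA
lurasidone,SGA
topiramate,anticonvulsant
oxcarbazepine,anticonvulsant
carbamazepine,anticonvulsant
levetiracetam,anticonvulsant
clonazepam,anxiolytic
lorazepam,anxiolytic
alprazolam,anxiolytic
diazepam,anxiolytic
hydroxyzine,anxiolytic
buspirone,anxiolytic
zolpidem,hypnotic/sedative
eszopiclone,hypnotic/sedative
temazepam,hypnotic/sedative
melatonin,hypnotic/sedative
methylphenidate,stimulant
amphetamine/dextroamphetamine,stimulant
lisdexamfetamine,stimulant
modafinil,stimulant
ibuprofen,analgesic
acetaminophen,analgesic
naproxen,analgesic
tramadol,analgesic
naltrexone,SUD drug
buprenorphine,SUD drug
acamprosate,SUD drug
disulfiram,SUD drug
varenicline,SUD drug
lamotrigine,mood stabiliser
gabapentin,mood stabiliser
valproate,mood stabiliser
lithium,mood stabiliser
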