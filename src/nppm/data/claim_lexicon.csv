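pattern,type
no added sugar,nutrition
no added sugars,nutrition
low in sugar,nutrition
low sugar,nutrition
sugar free,nutrition
no added salt,nutrition
low in salt,nutrition
source of fibre,nutrition
high in fibre,nutrition
source of protein,nutrition
high in protein,nutrition
source of vitamin,nutrition
source of vitamins,nutrition
source of iron,nutrition
source of calcium,nutrition
source of omega,nutrition
1 of your 5 a day,nutrition
one of your 5 a day,nutrition
one of their 5 a day,nutrition
no preservatives,nutrition
no artificial,nutrition
supports healthy growth,health
healthy growth,health
aids development,health
supports development,health
brain development,health
immune,health
healthy bones,health
strong bones,health
good for,health
growing up strong,health
gut health,health
organic,marketing
natural,marketing
naturally,marketing
tasty,marketing
yummy,marketing
delicious,marketing
scrummy,marketing
wholesome,marketing
perfect for little hands,marketing
little hands,marketing
kids love,marketing
made with love,marketing
fun,marketing
handpicked,marketing
goodness,marketing
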