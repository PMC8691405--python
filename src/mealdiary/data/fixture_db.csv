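code,source,description,brand,energy_kcal,protein_g,fat_g,carbohydrate_g,alcohol_g,portions
REF00001,reference,oatmeal,,233.466233645186,17.26419528993043,9.655652853121113,19.37714420184357,0.0,slice:30;plate:300;gram:1
REF00002,reference,pizza,,49.716953803108524,2.3474948293995217,1.8468333940473955,5.926368484770968,0.0,scoop:35;handful:30;gram:1
REF00003,reference,rice,,357.96452978818775,24.250064061121865,3.207911966200064,58.023266461974934,0.0,piece:50;slice:30;gram:1
REF00004,reference,bacon,,337.2479615510064,21.914138966602554,15.290915647711675,27.993291213797797,0.0,bowl:350;gram:1
REF00005,reference,eggs,,387.10592244267457,11.5600875092918,7.60192577254098,68.11206011315964,0.0,cup:240;gram:1
REF00006,reference,yogurt,,180.89909607999186,7.750984799793148,11.22188831772888,12.22454050531484,0.0,scoop:35;tablespoon:15;gram:1
REF00007,reference,bagel,,368.31434460552714,14.134253272168307,18.262843672417816,36.85293461627341,0.0,scoop:35;plate:300;bowl:350;gram:1
REF00008,reference,crackers,,61.0322595461687,0.3803228491704679,3.74608762500517,6.449044881110077,0.0,glass:250;gram:1
REF00009,reference,milk,,386.1483253815889,17.07474444429279,9.558072417948686,57.95667396071988,0.0,slice:30;cup:240;gram:1
REF00010,reference,carrots,,162.5849814372106,12.718464318032192,3.8173530823923887,19.338736605887583,0.0,scoop:35;handful:30;gram:1
REF00011,reference,blueberry carrots,,380.71558047122215,22.268173150495564,14.669796259561915,39.90368038329567,0.0,serving:150;gram:1
REF00012,reference,sourdough steak,,98.74967166039438,6.128189905647733,2.6576516424421928,12.57951181395593,0.0,plate:300;gram:1
REF00013,reference,mixed pizza,,216.5989906647955,2.5759281136643413,2.7500834185270837,45.3861318608486,0.0,piece:50;tablespoon:15;gram:1
REF00014,reference,sesame soda,,377.5049660976489,8.406042971989121,12.589693721189224,57.64338767974735,0.0,serving:150;bowl:350;plate:300;gram:1
REF00015,reference,skim apple,,389.8288181701736,22.15975128222798,13.684338841572531,44.50769086677721,0.0,cup:240;scoop:35;slice:30;gram:1
REF00016,reference,greek banana,,175.18334509022432,15.514586173891034,7.093411003456615,12.321075340887665,0.0,plate:300;tablespoon:15;gram:1
REF00017,reference,peanut shrimp,,84.93266262200498,10.140820588958162,1.4623259702922862,7.802111633385438,0.0,glass:250;gram:1
REF00018,reference,coconut juice,,162.88991302826437,5.399526634739311,5.1237888813196,23.79442663935768,0.0,plate:300;gram:1
REF00019,reference,mixed broccoli,,352.01728846861926,9.173905326815815,11.581060528950573,52.7730306002002,0.0,scoop:35;glass:250;serving:150;gram:1
REF00020,reference,herb muffin,,276.2959982461765,11.77018063620268,12.26709217861082,29.702861523467103,0.0,scoop:35;plate:300;cup:240;gram:1
REF00021,reference,green bacon,,113.30857802585045,1.191637763233645,5.857327794255759,13.95651920615351,0.0,tablespoon:15;gram:1
REF00022,reference,green cookie,,51.14518677157995,2.0021169504995684,0.9455577588119211,8.656674785068597,0.0,serving:150;handful:30;glass:250;gram:1
REF00023,reference,herb soda,,286.95880019794186,23.421641489021358,13.953874099299991,16.92184183703913,0.0,serving:150;gram:1
REF00024,reference,mushroom granola,,238.23546874569763,10.317194733410286,3.8647918610899947,40.54589076556163,0.0,tablespoon:15;gram:1
REF00025,reference,greek yogurt,,259.4990838939066,7.805615433876765,1.6294608965255004,53.402868522417506,0.0,serving:150;piece:50;bottle:500;gram:1
REF00026,reference,peanut cheese,,131.8532551283772,3.7749909605357885,2.7096099232422275,23.0917004942635,0.0,slice:30;gram:1
BRA00027,branded,greek shrimp,,306.1760506092731,25.06777928169334,12.39346911924914,23.590927852314362,0.0,slice:30;piece:50;gram:1
BRA00028,branded,sourdough quinoa,acme,141.68343923985532,5.0601011781506715,10.496946318052835,6.742629416194279,0.0,handful:30;serving:150;glass:250;gram:1
BRA00029,branded,coconut burrito,bluebird,179.07266744074929,14.996467702203729,10.062192602536324,7.13176580227686,0.0,can:355;glass:250;tablespoon:15;gram:1
BRA00030,branded,lemon chicken,,269.5542186726468,36.83285965423429,2.598225489686243,24.70968766213335,0.0,bottle:500;bowl:350;gram:1
BRA00031,branded,sesame tofu,mornington,150.930579992265,1.7269879436497384,8.893941873887648,15.994287838169306,0.0,slice:30;can:355;gram:1
BRA00032,branded,garlic carrots,redbarn,217.92130862632496,6.154751565088011,2.22556971599258,43.31804373050992,0.0,slice:30;bottle:500;gram:1
BRA00033,branded,mushroom lentils,bluebird,102.05501584269422,2.5627548057665797,5.964318276262131,9.53128303331718,0.0,scoop:35;tablespoon:15;can:355;gram:1
BRA00034,branded,white sandwich,,269.4116715753422,4.181154458524415,2.7406913584056296,57.005207878898474,0.0,bowl:350;piece:50;gram:1
BRA00035,branded,veggie chicken,redbarn,84.12898992845798,7.0468523151668006,3.36696254998397,6.409729429483763,0.0,bowl:350;serving:150;plate:300;gram:1
BRA00036,branded,green milk,acme,124.97133666045126,7.923333643925353,2.344975891738379,18.04330476477611,0.0,bottle:500;can:355;bowl:350;gram:1
BRA00037,branded,berry butter,bluebird,67.8876095886185,1.2721839262014618,5.77898187099502,2.6970092612143666,0.0,bottle:500;tablespoon:15;serving:150;gram:1
BRA00038,branded,garlic steak,harvest hill,138.5607429709479,4.580902072737145,4.4623599117044135,20.018973868664897,0.0,slice:30;gram:1
BRA00039,branded,onion pizza,mornington,96.87856980924066,2.762350658777848,4.366541565609449,11.632573270911053,0.0,can:355;tablespoon:15;gram:1
BRA00040,branded,cinnamon juice,,372.0058284069597,9.3708770089712,12.795917608730838,54.83976547312436,0.0,slice:30;gram:1
BRA00041,branded,swiss rice,,261.09632803894954,33.477111645142664,4.459581894480736,21.76291110201306,0.0,scoop:35;cup:240;bowl:350;gram:1
BRA00042,branded,herb chicken,acme,387.39309626628875,16.769673153423096,5.81921831152711,66.98535971221308,0.0,can:355;glass:250;piece:50;gram:1
BRA00043,branded,wheat beef,goldcrest,183.49836713246137,19.33117980231621,5.147358503296525,14.961855348381947,0.0,bottle:500;gram:1
BRA00044,branded,oatmeal,redbarn,230.6584697497944,2.758902107776755,15.352509205884274,20.36256961643223,0.0,serving:150;gram:1
REF90001,reference,"Cheese, cheddar",,403,23,33,3,0,slice:28;cup:132;gram:1
REF90002,reference,"Cheese, swiss",,380,27,28,5,0,slice:28;gram:1
REF90003,reference,"Bread, wheat",,247,13,3.5,41,0,slice:29;gram:1
REF90004,reference,chili,,95,7,3.5,9,0,bowl:350;cup:240;gram:1
REF90005,reference,milk,,61,3.2,3.3,4.8,0,cup:244;glass:250;gram:1
BRD90005,branded,milk,sunnyvale,64,3.3,3.6,4.9,0,cup:244;bottle:500;gram:1
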